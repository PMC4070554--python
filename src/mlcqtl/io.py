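"""Readers, writers and report generation.

One dialect everywhere: tab-delimited text with a one-line header and the
string ``NA`` for missing values.  Readers cross-validate consistency
(marker sets match between map and genotypes, every line has a family,
genotype values are 0/2/NA) and raise :class:`ValidationError` naming the
offending row.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DHPopulation, FamilySpec, GeneticMap, ValidationError
from .crossval import CVResult
from .scan import QTLRecord
from .simpop import PhenotypeSet

log = logging.getLogger(__name__)

__all__ = [
    "write_map",
    "read_map",
    "write_genotypes",
    "write_families",
    "write_phenotypes",
    "read_phenotypes",
    "read_population",
    "write_qtl_table",
    "write_scan_profile",
    "write_report",
]

_NA = "NA"


def write_map(gmap: GeneticMap, path) -> None:
    df = pd.DataFrame(
        {
            "group": [gmap.groups[g] for g in gmap.marker_group],
            "marker": list(gmap.marker_ids),
            "pos_cM": gmap.marker_pos,
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "marker": str})
    for col in ("group", "marker", "pos_cM"):
        if col not in df.columns:
            raise ValidationError(f"map file missing column {col!r}")
    return GeneticMap.from_records(
        [(r.group, r.marker, float(r.pos_cM)) for r in df.itertuples()]
    )


def write_genotypes(pop: DHPopulation, path) -> None:
    df = pd.DataFrame(pop.genotypes, columns=list(pop.gmap.marker_ids))
    df.insert(0, "line", list(pop.line_ids))
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.0f")


def write_families(pop: DHPopulation, path) -> None:
    fams = pop.families
    df = pd.DataFrame(
        {
            "line": list(pop.line_ids),
            "family": [fams[f].family_id for f in pop.line_family],
            "parent_a": [fams[f].parent_a_id for f in pop.line_family],
            "parent_b": [fams[f].parent_b_id for f in pop.line_family],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes(phenos: dict[str, PhenotypeSet], path) -> None:
    rows = []
    for stage, ps in phenos.items():
        n, E, R = ps.values.shape
        for e in range(E):
            env = "_".join(ps.environments[e])
            for r in range(R):
                for i in range(n):
                    rows.append((ps.line_ids[i], stage, env, r + 1, ps.values[i, e, r]))
    pd.DataFrame(rows, columns=["line", "stage", "environment", "rep", "value"]).to_csv(
        path, sep="\t", index=False, na_rep=_NA
    )


def read_phenotypes(path) -> dict[str, PhenotypeSet]:
    df = pd.read_csv(path, sep="\t", dtype={"line": str, "stage": str, "environment": str})
    out: dict[str, PhenotypeSet] = {}
    for stage, sub in df.groupby("stage", sort=False):
        lines = list(dict.fromkeys(sub["line"]))
        envs = list(dict.fromkeys(sub["environment"]))
        reps = sorted(sub["rep"].unique())
        cube = np.full((len(lines), len(envs), len(reps)), np.nan)
        li = {x: i for i, x in enumerate(lines)}
        ei = {x: i for i, x in enumerate(envs)}
        ri = {x: i for i, x in enumerate(reps)}
        for r in sub.itertuples():
            cube[li[r.line], ei[r.environment], ri[r.rep]] = r.value
        out[str(stage)] = PhenotypeSet(
            stage=str(stage),
            values=cube,
            environments=tuple(tuple(e.split("_", 1)) for e in envs),
            reps_per_env=len(reps),
            entry_means=np.nanmean(cube.reshape(len(lines), -1), axis=1),
            line_ids=tuple(lines),
        )
    return out


def read_population(map_path, geno_path, family_path) -> DHPopulation:
    """Assemble and cross-validate a population from the three data files.

    Genotype columns may be in any order; the map defines the order used.
    """
    gmap = read_map(map_path)
    geno = pd.read_csv(geno_path, sep="\t", dtype={"line": str})
    fam = pd.read_csv(family_path, sep="\t", dtype=str)
    missing = set(gmap.marker_ids) - set(geno.columns)
    if missing:
        raise ValidationError(f"genotype file lacks mapped markers: {sorted(missing)[:5]} ...")
    unknown = set(geno.columns) - {"line"} - set(gmap.marker_ids)
    if unknown:
        raise ValidationError(f"genotype file has unmapped markers: {sorted(unknown)[:5]} ...")
    fam_of = dict(zip(fam["line"], fam["family"]))
    orphans = [l for l in geno["line"] if l not in fam_of]
    if orphans:
        raise ValidationError(f"lines without family assignment: {orphans[:5]} ...")
    fam_ids = list(dict.fromkeys(fam["family"]))
    specs = []
    for f in fam_ids:
        rows = fam[fam["family"] == f]
        specs.append(
            FamilySpec(
                family_id=f,
                n_lines=int((geno["line"].map(fam_of) == f).sum()),
                parent_a_id=rows["parent_a"].iloc[0],
                parent_b_id=rows["parent_b"].iloc[0],
            )
        )
    G = geno[list(gmap.marker_ids)].to_numpy(dtype=float)
    bad = ~(np.isnan(G) | (G == 0.0) | (G == 2.0))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"row {i + 2} of genotype file: line {geno['line'].iloc[i]!r}, marker "
            f"{gmap.marker_ids[j]!r} has value {G[i, j]!r} (allowed: 0, 2, NA)"
        )
    line_family = np.array([fam_ids.index(fam_of[l]) for l in geno["line"]], dtype=np.intp)
    return DHPopulation(
        gmap=gmap,
        families=tuple(specs),
        genotypes=G,
        line_ids=tuple(geno["line"]),
        line_family=line_family,
    )


# -- result tables -------------------------------------------------------------


def qtl_frame(qtl: list[QTLRecord], family_ids: list[str]) -> pd.DataFrame:
    cols = {
        "stage": [q.stage for q in qtl],
        "group": [q.group for q in qtl],
        "peak_pos_cM": [q.peak_pos_cM for q in qtl],
        "support_lo": [q.support_lo for q in qtl],
        "support_hi": [q.support_hi for q in qtl],
        "LOD": [q.lod for q in qtl],
        "pG_single": [q.pG_single for q in qtl],
    }
    for p, f in enumerate(family_ids):
        cols[f"effect_{f}"] = [q.effects[p] for q in qtl]
    return pd.DataFrame(cols)


def write_qtl_table(qtl: list[QTLRecord], family_ids: list[str], path) -> None:
    qtl_frame(qtl, family_ids).to_csv(path, sep="\t", index=False, na_rep=_NA)


def write_scan_profile(result, family_ids: list[str], path) -> None:
    grid = result.grid
    df = pd.DataFrame(
        {
            "group": [grid.groups[g] for g in grid.group_idx],
            "pos_cM": grid.pos,
            "LOD": result.lod,
        }
    )
    for p, f in enumerate(family_ids):
        df[f"effect_{f}"] = result.effects[:, p]
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def write_report(
    out_dir,
    family_ids: list[str],
    qtl_by_stage: dict[str, list[QTLRecord]],
    pg_combined: dict[str, float],
    cv_by_stage: dict[str, CVResult],
    venn_counts: dict[tuple[str, ...], int],
    pg_matrix: pd.DataFrame | None,
    run_info: dict,
) -> None:
    """Write the stage-wise QTL tables, the cross-validation summary, the
    overlap (Venn) counts, the locus x stage p_G matrix and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(qtl_by_stage)
    all_qtl = [q for s in stages for q in qtl_by_stage[s]]
    write_qtl_table(all_qtl, family_ids, out / "qtl_table.tsv")
    rows = {
        "QTL_DS": [len(qtl_by_stage[s]) for s in stages],
        "pG_DS": [pg_combined.get(s, np.nan) for s in stages],
        "QTL_ES": [cv_by_stage[s].qtl_count_mean if s in cv_by_stage else np.nan for s in stages],
        "pG_ES": [cv_by_stage[s].pG_ES_mean if s in cv_by_stage else np.nan for s in stages],
        "pG_TS": [cv_by_stage[s].pG_TS_mean if s in cv_by_stage else np.nan for s in stages],
        "relative_bias": [
            cv_by_stage[s].relative_bias if s in cv_by_stage else np.nan for s in stages
        ],
    }
    pd.DataFrame(rows, index=stages).T.to_csv(
        out / "cv_summary.tsv", sep="\t", na_rep=_NA, index_label="quantity"
    )
    venn = pd.DataFrame(
        {
            "stages": ["+".join(k) for k in venn_counts],
            "n_qtl": list(venn_counts.values()),
        }
    )
    venn.to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    if pg_matrix is not None:
        pg_matrix.to_csv(out / "pg_by_stage.tsv", sep="\t", na_rep=_NA, index_label="locus")
    freq_rows = []
    for s in stages:
        if s in cv_by_stage:
            for (g, b), c in sorted(cv_by_stage[s].frequency.items()):
                freq_rows.append((s, g, b, c, cv_by_stage[s].n_runs))
    pd.DataFrame(
        freq_rows, columns=["stage", "group", "bin_start_cM", "count", "n_runs"]
    ).to_csv(out / "qtl_frequency.tsv", sep="\t", index=False)
    with open(out / "run_log.txt", "w") as fh:
        for k, v in run_info.items():
            fh.write(f"{k}\t{v}\n")
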