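"""End-to-end orchestration: simulate -> phenotype statistics -> stage-wise
QTL scans -> cross-validation -> epistasis -> report.

The default configuration emulates the reference study design at desk
scale: four DH families of 131/120/200/196 lines on a 21-group map, three
correlated developmental stages of one trait, entry-mean heritabilities in
the 0.8-0.9 range over four environments and genotype-by-environment
variance between a third and a seventh of the genotypic variance.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import run_cv
from .epistasis import epistasis_scan, region_threshold
from .genoprob import expected_counts, make_grid
from .phenostats import compute_blues, heritability, stage_correlations, variance_components
from .scan import ScanEngine, classify_overlap, declare_qtl, QTLRecord
from . import io as mio
from .simpop import (
    STAGES,
    restrict_to_map,
    simulate_phenotypes,
    simulate_population,
    study_architecture,
    study_families,
    study_map,
)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "mlcqtl_out",
    "stages": list(STAGES),
    "map": {"n_groups": 21, "length_cm": 150.0, "spacing_cm": 5.0},
    "h2": {"BM1": 0.81, "BM2": 0.91, "BM3": 0.87},
    "ge_ratio": {"BM1": 3.0, "BM2": 7.0, "BM3": 5.0},
    "n_env": 4,
    "reps_per_env": 2,
    "scan": {"step_cm": 1.0, "alpha": 0.10, "n_perm": 200, "max_cofactors": 10},
    "cv": {"k": 5, "n_replicates": 4},
    "epistasis": {"enabled": True, "step_cm": 10.0, "alpha": 0.05},
}


def load_config(path=None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    return cfg


def simulate_study(cfg: dict):
    """Simulate the default study emulation: population + stage phenotypes."""
    m = cfg["map"]
    gmap = study_map(int(m["n_groups"]), float(m["length_cm"]), float(m["spacing_cm"]))
    arch = restrict_to_map(study_architecture(), gmap)
    pop = simulate_population(gmap, study_families(), seed=int(cfg["seed"]), arch=arch)
    phenos = {}
    for si, stage in enumerate(cfg["stages"]):
        phenos[stage] = simulate_phenotypes(
            pop,
            arch,
            stage,
            h2_target=float(cfg["h2"][stage]),
            ge_ratio=float(cfg["ge_ratio"][stage]),
            n_env=int(cfg["n_env"]),
            reps_per_env=int(cfg["reps_per_env"]),
            seed=int(cfg["seed"]) * 1000 + si,
        )
    return pop, arch, phenos


def phenostats_report(phenos: dict, out_path=None) -> pd.DataFrame:
    rows = []
    blues = {}
    for stage, ps in phenos.items():
        vc = variance_components(ps.values)
        h2 = heritability(vc).h2
        blues[stage] = compute_blues(ps.values)
        rows.append(
            {
                "stage": stage,
                "sigma2_G": vc.sigma2_G,
                "sigma2_GE": vc.sigma2_GE,
                "sigma2_e": vc.sigma2_e,
                "G_to_GE_ratio": vc.sigma2_G / vc.sigma2_GE if vc.sigma2_GE > 0 else np.inf,
                "h2": h2,
            }
        )
    df = pd.DataFrame(rows).set_index("stage")
    if out_path is not None:
        df.to_csv(out_path, sep="\t", na_rep="NA")
        corr, _ = stage_correlations(blues)
        corr.to_csv(str(out_path).replace(".tsv", "_correlations.tsv"), sep="\t")
    return df


def run_all(cfg: dict) -> dict:
    """Execute the full pipeline per the configuration; returns all results."""
    out = Path(cfg["out_dir"])
    (out / "data").mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    pop, arch, phenos = simulate_study(cfg)
    mio.write_map(pop.gmap, out / "data" / "map.tsv")
    mio.write_genotypes(pop, out / "data" / "genotypes.tsv")
    mio.write_families(pop, out / "data" / "families.tsv")
    mio.write_phenotypes(phenos, out / "data" / "phenotypes.tsv")

    stats = phenostats_report(phenos, out / "phenostats.tsv")
    scan_cfg, cv_cfg, epi_cfg = cfg["scan"], cfg["cv"], cfg["epistasis"]
    grid = make_grid(pop.gmap, float(scan_cfg["step_cm"]))
    engine = ScanEngine(pop, expected_counts(pop, grid))
    fam_ids = [f.family_id for f in pop.families]

    qtl_by_stage: dict[str, list[QTLRecord]] = {}
    pg_combined: dict[str, float] = {}
    cv_by_stage = {}
    thresholds = {}
    epi_tables = []
    for si, stage in enumerate(cfg["stages"]):
        y = phenos[stage].entry_means
        h2 = float(stats.loc[stage, "h2"])
        perm = engine.permutation_threshold(
            y,
            n_perm=int(scan_cfg["n_perm"]),
            alpha=float(scan_cfg["alpha"]),
            seed=seed * 100 + si,
            max_cofactors=int(scan_cfg["max_cofactors"]),
        )
        thresholds[stage] = perm.threshold
        cof = engine.select_cofactors(y, int(scan_cfg["max_cofactors"]))
        res = engine.scan(y, cof)
        mio.write_scan_profile(res, fam_ids, out / f"scan_{stage}.tsv")
        qtl = declare_qtl(res, perm.threshold, stage=stage)
        if qtl:
            combined, singles = engine.proportion_genotypic_variance(qtl, y, h2)
            pg_combined[stage] = combined
            for q, s in zip(qtl, singles):
                q.pG_single = s
        else:
            pg_combined[stage] = 0.0
        qtl_by_stage[stage] = qtl
        cv_by_stage[stage] = run_cv(
            engine,
            y,
            h2,
            perm.threshold,
            k=int(cv_cfg["k"]),
            n_replicates=int(cv_cfg["n_replicates"]),
            seed=seed * 10 + si,
            max_cofactors=int(scan_cfg["max_cofactors"]),
        )
        if epi_cfg.get("enabled", True):
            egrid = make_grid(pop.gmap, float(epi_cfg["step_cm"]))
            eengine = ScanEngine(pop, expected_counts(pop, egrid))
            thr = region_threshold(len(pop.gmap.groups), float(epi_cfg["alpha"]))
            for rec in epistasis_scan(eengine, y, thr, h2=h2):
                epi_tables.append(
                    (
                        stage,
                        rec.locus1[0],
                        rec.locus1[1],
                        rec.locus2[0],
                        rec.locus2[1],
                        rec.p_value,
                        rec.neglog10p,
                        rec.pG_epi,
                    )
                )

    venn, clusters = classify_overlap(qtl_by_stage)
    pg_matrix = _pg_by_stage_matrix(engine, phenos, stats, clusters, cfg["stages"])
    run_info = {
        "mlcqtl_version": __version__,
        "seed": seed,
        "n_lines": pop.n_lines,
        **{f"threshold_{s}": f"{t:.3f}" for s, t in thresholds.items()},
    }
    mio.write_report(
        out, fam_ids, qtl_by_stage, pg_combined, cv_by_stage, venn, pg_matrix, run_info
    )
    if epi_tables:
        pd.DataFrame(
            epi_tables,
            columns=[
                "stage", "group1", "pos1_cM", "group2", "pos2_cM", "P", "neglog10P", "pG_epi",
            ],
        ).to_csv(out / "epistasis.tsv", sep="\t", index=False, na_rep="NA")
    return {
        "population": pop,
        "phenostats": stats,
        "thresholds": thresholds,
        "qtl_by_stage": qtl_by_stage,
        "pg_combined": pg_combined,
        "cv_by_stage": cv_by_stage,
        "venn": venn,
    }


def _pg_by_stage_matrix(engine, phenos, stats, clusters, stages) -> pd.DataFrame | None:
    """Locus x stage matrix of single-locus p_G shares (temporal dynamics)."""
    reps = []
    for members in clusters:
        best = max(members, key=lambda m: m[1].lod)[1]
        reps.append((best.group, best.peak_pos_cM))
    if not reps:
        return None
    rows = {}
    for stage in stages:
        y = phenos[stage].entry_means
        h2 = float(stats.loc[stage, "h2"])
        recs = [QTLRecord(g, p, p, p, 0.0, np.zeros(engine.P)) for g, p in reps]
        _, singles = engine.proportion_genotypic_variance(recs, y, h2)
        rows[stage] = singles
    idx = [f"{g}@{p:g}cM" for g, p in reps]
    return pd.DataFrame(rows, index=idx)
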