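"""Synthetic multi-family DH study generator.

Emulates the design of a multi-family doubled-haploid mapping study of a
dynamic trait: four biparental DH families genotyped on a shared multi-group
linkage map, a planted QTL architecture whose effects are family-specific
and scale with developmental stage, and multi-environment phenotypes with a
controlled entry-mean heritability and a controlled ratio of genotypic to
genotype-by-environment variance.

Gametes are simulated as a two-state Markov chain along each linkage group
(Haldane mapping function, no interference) and doubled, so every line is
fully homozygous.  Planted QTL need not sit on markers: their true genotypes
are simulated on the same gamete and kept as latent loci on the population
object, which lets downstream scans be judged against truth at off-marker
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import DHPopulation, FamilySpec, GeneticMap, ParameterError
from .genoprob import haldane_r

__all__ = [
    "make_map",
    "simulate_dh_family",
    "simulate_population",
    "AdditiveQTL",
    "EpistaticQTL",
    "QTLArchitecture",
    "genetic_values",
    "parent_genetic_values",
    "architecture_variance_shares",
    "PhenotypeSet",
    "simulate_phenotypes",
    "inject_missing",
    "study_families",
    "study_map",
    "study_architecture",
    "STAGES",
]

STAGES = ("BM1", "BM2", "BM3")


def make_map(
    n_groups: int, group_length_cM: float, marker_spacing_cM: float, seed: int = 0
) -> GeneticMap:
    """Equally spaced marker map: markers at 0, s, 2s, ... per group.

    Deterministic; ``seed`` is accepted for interface uniformity only.
    """
    if n_groups < 1 or group_length_cM <= 0 or marker_spacing_cM <= 0:
        raise ParameterError("n_groups, group_length_cM and marker_spacing_cM must be positive")
    if group_length_cM < marker_spacing_cM:
        raise ParameterError("group length must be at least one marker spacing")
    records = []
    for gi in range(n_groups):
        g = f"LG{gi + 1}"
        pos = np.arange(0.0, group_length_cM + 1e-9, marker_spacing_cM)
        for k, p in enumerate(pos):
            records.append((g, f"{g}_m{k + 1}", float(p)))
    return GeneticMap.from_records(records)


def _simulate_gametes(
    positions_per_group: list[np.ndarray], n_lines: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean matrix (line x locus): True where the doubled gamete carries allele A."""
    blocks = []
    for pos in positions_per_group:
        m = pos.size
        allele = np.empty((n_lines, m), dtype=bool)
        allele[:, 0] = rng.random(n_lines) < 0.5
        if m > 1:
            r = haldane_r(np.diff(pos))
            switch = rng.random((n_lines, m - 1)) < r[None, :]
            # cumulative XOR of switch events propagates the parental origin
            flips = np.cumsum(switch, axis=1) % 2 == 1
            allele[:, 1:] = allele[:, [0]] ^ flips
        blocks.append(allele)
    return np.concatenate(blocks, axis=1)


def simulate_dh_family(gmap: GeneticMap, spec: FamilySpec, seed: int) -> np.ndarray:
    """Genotype block (n_lines x n_markers, coded 0/2) for one DH family."""
    rng = np.random.default_rng(seed)
    pos = [gmap.marker_pos[gmap.group_slices[g]] for g in gmap.groups]
    allele = _simulate_gametes(pos, spec.n_lines, rng)
    return np.where(allele, 2.0, 0.0)


@dataclass(frozen=True)
class AdditiveQTL:
    """One planted additive locus with family-specific allele-substitution effects.

    ``effects[p]`` is the effect of one parent-A allele in family p (trait
    units per allele); 0 means the locus does not segregate for the trait in
    that family.  ``stage_scale`` multiplies the effect per developmental
    stage (absent stage -> 1.0), modelling temporal QTL dynamics.
    """

    group: str
    pos_cM: float
    effects: tuple[float, ...]
    stage_scale: Mapping[str, float] = field(default_factory=dict)

    def scale(self, stage: str) -> float:
        return float(self.stage_scale.get(stage, 1.0))


@dataclass(frozen=True)
class EpistaticQTL:
    """A planted two-locus interaction with family-specific effects."""

    locus1: tuple[str, float]
    locus2: tuple[str, float]
    effects: tuple[float, ...]
    stage_scale: Mapping[str, float] = field(default_factory=dict)

    def scale(self, stage: str) -> float:
        return float(self.stage_scale.get(stage, 1.0))


@dataclass(frozen=True)
class QTLArchitecture:
    additive: tuple[AdditiveQTL, ...] = ()
    epistatic: tuple[EpistaticQTL, ...] = ()
    family_means: tuple[float, ...] | None = None  # default: all zero

    def loci(self) -> list[tuple[str, float]]:
        out: list[tuple[str, float]] = []
        for q in self.additive:
            out.append((q.group, q.pos_cM))
        for e in self.epistatic:
            out.extend([e.locus1, e.locus2])
        seen: list[tuple[str, float]] = []
        for loc in out:
            if loc not in seen:
                seen.append(loc)
        return seen


def simulate_population(
    gmap: GeneticMap,
    families: tuple[FamilySpec, ...],
    seed: int,
    arch: QTLArchitecture | None = None,
) -> DHPopulation:
    """Simulate all families on a shared map; deterministic given seed.

    When an architecture is given, its loci are simulated jointly with the
    markers on the same gametes and stored as latent loci (true genotypes at
    the planted QTL positions).
    """
    extra = arch.loci() if arch is not None else []
    for g, p in extra:
        lo, hi = gmap.span(g)
        if not lo <= p <= hi:
            raise ParameterError(f"QTL position {p} outside span of group {g}")
    rng = np.random.default_rng(seed)
    geno_blocks, extra_blocks, fam_idx, line_ids = [], [], [], []
    for fi, spec in enumerate(families):
        pos_per_group, is_marker, order = [], [], []
        for g in gmap.groups:
            mpos = list(gmap.marker_pos[gmap.group_slices[g]])
            epos = [p for gg, p in extra if gg == g]
            allpos = sorted(set(mpos) | set(epos))
            pos_per_group.append(np.array(allpos))
            for p in allpos:
                is_marker.append(p in mpos)
                order.append((g, p))
        allele = _simulate_gametes(pos_per_group, spec.n_lines, rng)
        codes = np.where(allele, 2.0, 0.0)
        is_marker_arr = np.array(is_marker)
        geno_blocks.append(codes[:, is_marker_arr])
        extra_cols = {}
        for j, (g, p) in enumerate(order):
            if (g, p) in extra:
                extra_cols[(g, p)] = codes[:, j]
        extra_blocks.append(extra_cols)
        fam_idx.append(np.full(spec.n_lines, fi, dtype=np.intp))
        line_ids.extend(f"{spec.family_id}_{i + 1:03d}" for i in range(spec.n_lines))
    latent = {
        loc: np.concatenate([b[loc] for b in extra_blocks]) for loc in extra
    }
    return DHPopulation(
        gmap=gmap,
        families=families,
        genotypes=np.concatenate(geno_blocks, axis=0),
        line_ids=tuple(line_ids),
        line_family=np.concatenate(fam_idx),
        latent_loci=latent,
    )


def _locus_codes(pop: DHPopulation, locus: tuple[str, float]) -> np.ndarray:
    """True 0/2 codes at a planted locus (latent if off-marker, else the marker)."""
    if locus in pop.latent_loci:
        return pop.latent_loci[locus]
    g, p = locus
    sl = pop.gmap.group_slices[g]
    mpos = pop.gmap.marker_pos[sl]
    j = int(np.argmin(np.abs(mpos - p)))
    if abs(mpos[j] - p) > 1e-9:
        raise ParameterError(f"no simulated genotype at locus {locus}")
    return pop.genotypes[:, sl.start + j]


def genetic_values(pop: DHPopulation, arch: QTLArchitecture, stage: str) -> np.ndarray:
    """True genetic value per line: family mean + additive + epistatic terms.

    Additive term per QTL: effect * (count - 1), i.e. +-effect for the two
    homozygotes; epistatic term: effect * (c1 - 1) * (c2 - 1).
    """
    P = len(pop.families)
    mu = np.zeros(P) if arch.family_means is None else np.asarray(arch.family_means, float)
    g = mu[pop.line_family].astype(float).copy()
    fam = pop.line_family
    for q in arch.additive:
        x = _locus_codes(pop, (q.group, q.pos_cM)) - 1.0
        g += q.scale(stage) * np.asarray(q.effects, float)[fam] * x
    for e in arch.epistatic:
        x1 = _locus_codes(pop, e.locus1) - 1.0
        x2 = _locus_codes(pop, e.locus2) - 1.0
        g += e.scale(stage) * np.asarray(e.effects, float)[fam] * x1 * x2
    return g


def parent_genetic_values(
    arch: QTLArchitecture, stage: str, family_index: int
) -> tuple[float, float]:
    """Genetic values of the two parents of one family (parent A all-2, B all-0)."""
    mu = 0.0 if arch.family_means is None else float(arch.family_means[family_index])
    gA = gB = mu
    for q in arch.additive:
        a = q.scale(stage) * q.effects[family_index]
        gA += a
        gB -= a
    for e in arch.epistatic:
        w = e.scale(stage) * e.effects[family_index]
        gA += w  # (+1)(+1)
        gB += w  # (-1)(-1)
    return gA, gB


def architecture_variance_shares(
    pop: DHPopulation, arch: QTLArchitecture, stage: str
) -> dict[tuple[str, float], float]:
    """Realized share of genetic variance per additive QTL (planted p_G, fraction).

    Computed from the simulated latent genotypes: Var(term_q) / Var(g) over
    all lines.  Shares need not sum to 1 when loci are linked or epistasis
    is present.
    """
    g = genetic_values(pop, arch, stage)
    vg = float(np.var(g, ddof=1))
    shares = {}
    fam = pop.line_family
    for q in arch.additive:
        term = q.scale(stage) * np.asarray(q.effects, float)[fam] * (
            _locus_codes(pop, (q.group, q.pos_cM)) - 1.0
        )
        shares[(q.group, q.pos_cM)] = float(np.var(term, ddof=1)) / vg if vg > 0 else 0.0
    return shares


@dataclass
class PhenotypeSet:
    """Per-environment phenotype values and entry means for one stage."""

    stage: str
    values: np.ndarray  # n_lines x n_env x reps_per_env
    environments: tuple[tuple[str, str], ...]  # (location, year) labels
    reps_per_env: int
    entry_means: np.ndarray
    line_ids: tuple[str, ...]


def _env_labels(n_env: int) -> tuple[tuple[str, str], ...]:
    return tuple((f"L{k % 2 + 1}", f"Y{k // 2 + 1}") for k in range(n_env))


def simulate_phenotypes(
    pop: DHPopulation,
    arch: QTLArchitecture,
    stage: str,
    h2_target: float,
    ge_ratio: float,
    n_env: int = 4,
    reps_per_env: int = 2,
    seed: int = 0,
) -> PhenotypeSet:
    """Phenotypes with controlled entry-mean heritability and sigma2_G:sigma2_GE ratio.

    The genetic variance is estimated empirically from the realized genetic
    values g; then sigma2_GE = sigma2_G / ge_ratio and the plot error
    variance is solved from
    h2 = sigma2_G / (sigma2_G + sigma2_GE/E + sigma2_e/(E*r)).
    ``ge_ratio=inf`` requests no G-by-E variance.
    """
    if not 0.0 < h2_target <= 1.0:
        raise ParameterError("h2_target must lie in (0, 1]")
    if ge_ratio <= 0:
        raise ParameterError("ge_ratio must be > 0 (may be inf)")
    if n_env < 2:
        raise ParameterError("n_env must be >= 2")
    g = genetic_values(pop, arch, stage)
    s2g = float(np.var(g, ddof=1))
    if s2g <= 0:
        raise ParameterError(
            "architecture yields zero genetic variance; draw pure noise directly instead"
        )
    s2ge = 0.0 if np.isinf(ge_ratio) else s2g / ge_ratio
    E, r = n_env, reps_per_env
    s2e = E * r * (s2g / h2_target - s2g - s2ge / E)
    if s2e < -1e-9 * s2g:
        raise ParameterError(
            f"h2_target {h2_target} unreachable with ge_ratio {ge_ratio} and {E} environments"
        )
    s2e = max(s2e, 0.0)
    rng = np.random.default_rng(seed)
    n = pop.n_lines
    ge = rng.normal(0.0, np.sqrt(s2ge), (n, E)) if s2ge > 0 else np.zeros((n, E))
    err = rng.normal(0.0, np.sqrt(s2e), (n, E, r)) if s2e > 0 else np.zeros((n, E, r))
    values = g[:, None, None] + ge[:, :, None] + err
    return PhenotypeSet(
        stage=stage,
        values=values,
        environments=_env_labels(E),
        reps_per_env=r,
        entry_means=values.mean(axis=(1, 2)),
        line_ids=pop.line_ids,
    )


def inject_missing(pop: DHPopulation, rate: float, seed: int) -> DHPopulation:
    """Copy of the population with genotype calls set missing at random."""
    if not 0.0 <= rate < 1.0:
        raise ParameterError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    geno = pop.genotypes.copy()
    geno[rng.random(geno.shape) < rate] = np.nan
    return DHPopulation(
        gmap=pop.gmap,
        families=pop.families,
        genotypes=geno,
        line_ids=pop.line_ids,
        line_family=pop.line_family,
        latent_loci=dict(pop.latent_loci),
    )


# --- default study emulation -------------------------------------------------
# Four DH families of 131/120/200/196 lines (647 total) on a 21-group map.
# Family 4 segregates for a dwarfing-locus-like major QTL whose influence is
# weak at the first stage, strongest at the second and attenuated at the
# third, producing the characteristic unimodal -> bimodal -> less pronounced
# within-family distribution across stages.


def restrict_to_map(arch: QTLArchitecture, gmap: GeneticMap) -> QTLArchitecture:
    """Drop architecture loci that fall outside the map (absent group or span).

    Lets the default study architecture run on smaller configured maps.
    """

    def on_map(loc: tuple[str, float]) -> bool:
        if loc[0] not in gmap.groups:
            return False
        lo, hi = gmap.span(loc[0])
        return lo <= loc[1] <= hi

    return QTLArchitecture(
        additive=tuple(q for q in arch.additive if on_map((q.group, q.pos_cM))),
        epistatic=tuple(
            e for e in arch.epistatic if on_map(e.locus1) and on_map(e.locus2)
        ),
        family_means=arch.family_means,
    )


def study_families() -> tuple[FamilySpec, ...]:
    sizes = (131, 120, 200, 196)
    return tuple(
        FamilySpec(f"FAM{i + 1}", n, f"P{i + 1}a", f"P{i + 1}b") for i, n in enumerate(sizes)
    )


def study_map(
    n_groups: int = 21, group_length_cM: float = 150.0, marker_spacing_cM: float = 5.0
) -> GeneticMap:
    return make_map(n_groups, group_length_cM, marker_spacing_cM)


def study_architecture(polygenic_background: bool = True) -> QTLArchitecture:
    """Default planted architecture: one stage-dynamic major QTL (~25-30% of
    the genetic variance), shared and stage-specific minor QTL, three
    epistatic pairs whose joint weight declines after the first stage, and a
    polygenic background of many sub-detection loci.

    The background (~30-40% of the genetic variance spread over ~40 small
    loci) models the part of a quantitative trait that individually escapes
    detection at a realistic population size; without it every unit of
    genetic variance would be attributable to mappable QTL and
    cross-validation could not show the overfitting bias real studies see.
    """
    up, down = {"BM1": 0.5, "BM2": 1.0, "BM3": 1.2}, {"BM1": 1.2, "BM2": 1.0, "BM3": 0.4}
    major = {"BM1": 0.35, "BM2": 1.0, "BM3": 0.6}
    # Family 4 mirrors a family segregating for a dominant dwarfing locus:
    # its major QTL dwarfs the rest of its genetic variance, so its minor
    # and background effects are kept small relative to the other families.
    additive = (
        # dwarfing-type major QTL, segregating only in family 4
        AdditiveQTL("LG15", 72.0, (0.0, 0.0, 0.0, 0.95), major),
        # stable QTL detected at every stage
        AdditiveQTL("LG5", 40.0, (0.45, 0.35, 0.40, 0.15)),
        AdditiveQTL("LG9", 105.0, (0.30, 0.40, 0.25, 0.18)),
        # QTL rising / declining with development
        AdditiveQTL("LG2", 60.0, (0.35, 0.0, 0.30, 0.12), up),
        AdditiveQTL("LG12", 20.0, (0.0, 0.35, 0.30, 0.0), down),
        # smaller, partly family-specific QTL
        AdditiveQTL("LG3", 115.0, (0.25, 0.20, 0.0, 0.10)),
        AdditiveQTL("LG7", 85.0, (0.20, 0.0, 0.25, 0.0), up),
        AdditiveQTL("LG17", 50.0, (0.0, 0.25, 0.20, 0.10), down),
        AdditiveQTL("LG19", 130.0, (0.20, 0.20, 0.0, 0.08)),
        AdditiveQTL("LG21", 10.0, (0.15, 0.0, 0.20, 0.10), up),
    )
    if polygenic_background:
        rng = np.random.default_rng(20140610)  # fixed: the background is part of the design
        bg = []
        for gi in range(21):
            for pos in (32.5, 117.5):
                eff = [rng.choice([-1.0, 1.0]) * rng.uniform(0.06, 0.13) for _ in range(4)]
                eff[3] *= 0.5
                scale = {s: float(rng.uniform(0.8, 1.2)) for s in STAGES}
                bg.append(AdditiveQTL(f"LG{gi + 1}", pos, tuple(eff), scale))
        additive = additive + tuple(bg)
    epi_down = {"BM1": 1.0, "BM2": 0.45, "BM3": 0.55}
    epistatic = (
        EpistaticQTL(("LG6", 55.0), ("LG10", 90.0), (0.20, 0.20, 0.15, 0.20), epi_down),
        EpistaticQTL(("LG1", 30.0), ("LG14", 70.0), (0.15, 0.20, 0.20, 0.0), epi_down),
        EpistaticQTL(("LG4", 100.0), ("LG16", 25.0), (0.20, 0.0, 0.15, 0.20)),
    )
    return QTLArchitecture(additive=additive, epistatic=epistatic)
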