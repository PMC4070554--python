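"""Two-dimensional epistasis scan.

The additive two-locus model (family means + family-specific allele counts
at loci q and q') is extended by a family-specific interaction block whose
column for family p is the elementwise product of the within-family
centered counts at the two loci.  The interaction block is tested with a
pooled F test (full vs. the same model without the block); multiplicity is
handled by a Bonferroni correction over independent chromosome-region
pairs, assuming two regions per linkage group.

As in the main scan, all design columns are family-supported, so the fit
decomposes per family and the 2-D grid is swept with vectorized rank-one
updates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .core import ParameterError
from .scan import ScanEngine, _basis

log = logging.getLogger(__name__)

__all__ = [
    "EpistasisRecord",
    "Landscape",
    "region_threshold",
    "pair_test",
    "epistasis_scan",
    "landscape",
]


@dataclass
class EpistasisRecord:
    """A significant two-locus interaction cluster (canonically ordered loci)."""

    locus1: tuple[str, float]
    locus2: tuple[str, float]
    p_value: float
    effects: np.ndarray  # per-family interaction effects
    pG_epi: float = float("nan")  # percent of genotypic variance
    stage: str | None = None

    @property
    def neglog10p(self) -> float:
        return float(-np.log10(self.p_value)) if self.p_value > 0 else np.inf


@dataclass
class Landscape:
    """Dense -log10(P) interaction surface for one chromosome pair."""

    group_a: str
    group_b: str
    pos_a: np.ndarray
    pos_b: np.ndarray
    neglog10p: np.ndarray  # len(pos_a) x len(pos_b)
    significant: np.ndarray  # boolean mask at the scan threshold
    threshold: float


def region_threshold(n_groups: int, alpha: float = 0.05) -> float:
    """Bonferroni P threshold over independent chromosome-region pairs.

    With two regions per linkage group there are C(2*n_groups, 2) possible
    pairwise interactions; the test-wise level is alpha divided by that.
    """
    if n_groups < 1:
        raise ParameterError("n_groups must be >= 1")
    return alpha / comb(2 * n_groups, 2)


def _tol(raw: np.ndarray) -> np.ndarray:
    return 1e-9 * (raw + 1.0)


def _pair_block(engine: ScanEngine, y: np.ndarray, i: int, J: np.ndarray) -> np.ndarray:
    """Interaction P values of locus column ``i`` against candidate columns ``J``.

    For every candidate: F test of the interaction block in
    means + x_i + x_j + x_i:x_j  vs  means + x_i + x_j, pooled over families.
    """
    n = engine.n
    rss_red = np.zeros(J.size)
    rss_full = np.zeros(J.size)
    df1 = np.zeros(J.size, dtype=int)
    k_full = np.zeros(J.size, dtype=int)
    for p, idx in enumerate(engine.fam_idx):
        yp = y[idx]
        C = engine.fam_counts[p]
        x1 = C[:, i]
        Q = _basis([np.ones(idx.size), x1])
        k_base = Q.shape[1]
        r = yp - Q @ (Q.T @ yp)
        rss_base = float(r @ r)
        X2 = C[:, J]
        x1c = x1 - x1.mean()
        X12 = x1c[:, None] * (X2 - X2.mean(axis=0))
        a = X2 - Q @ (Q.T @ X2)
        na2 = np.einsum("ij,ij->j", a, a)
        okA = na2 > _tol(np.einsum("ij,ij->j", X2, X2))
        na2s = np.where(okA, na2, 1.0)
        pa = a.T @ r
        red1 = np.where(okA, pa * pa / na2s, 0.0)
        b = X12 - Q @ (Q.T @ X12)
        ab = np.einsum("ij,ij->j", a, b)
        nb2 = np.einsum("ij,ij->j", b, b)
        bperp2 = nb2 - np.where(okA, ab * ab / na2s, 0.0)
        okB = bperp2 > _tol(np.einsum("ij,ij->j", X12, X12))
        pb = b.T @ r
        pb_after = pb - np.where(okA, ab * pa / na2s, 0.0)
        red2 = np.where(okB, pb_after * pb_after / np.where(okB, bperp2, 1.0), 0.0)
        rss_red += rss_base - red1
        rss_full += rss_base - red1 - red2
        df1 += okB
        k_full += k_base + okA.astype(int) + okB.astype(int)
    df2 = n - k_full
    # degeneracy floor scaled to the phenotype's energy (catches constant y,
    # where the residual is pure floating-point dust)
    floor = 1e-10 * (float(y @ y) + 1.0)
    ok = (df1 > 0) & (df2 > 0) & (rss_full > floor)
    F = np.where(ok, (rss_red - rss_full) / np.maximum(df1, 1), np.nan) / np.where(
        ok, rss_full / np.maximum(df2, 1), 1.0
    )
    P = np.ones(J.size)
    P[ok] = stats.f.sf(F[ok], df1[ok], df2[ok])
    return P


def pair_test(engine: ScanEngine, y: np.ndarray, col1: int, col2: int):
    """Interaction test of one locus pair: returns (P, per-family effects).

    Loci are ordered canonically first so the test is exactly symmetric in
    its arguments.  A family whose interaction column is collinear with the
    main effects is dropped from the tested block (df reduced); if that
    happens in every family, P = 1 with a logged reason.
    """
    if col1 == col2:
        raise ParameterError("the two loci must differ")
    i, j = sorted((col1, col2))
    y = np.asarray(y, dtype=float)
    P = float(_pair_block(engine, y, i, np.array([j]))[0])
    effects = np.zeros(engine.P)
    for p, idx in enumerate(engine.fam_idx):
        C = engine.fam_counts[p]
        x1, x2 = C[:, i], C[:, j]
        x12 = (x1 - x1.mean()) * (x2 - x2.mean())
        X = np.column_stack([np.ones(idx.size), x1, x2, x12])
        beta, *_ = np.linalg.lstsq(X, y[idx], rcond=None)
        effects[p] = beta[3]
    if P >= 1.0:
        log.info("interaction block collinear or uninformative for pair (%d, %d)", i, j)
    return P, effects


def _candidates(engine: ScanEngine, i: int, min_cm_same_group: float) -> np.ndarray:
    grid = engine.grid
    J = np.arange(i + 1, grid.n_positions)
    same = grid.group_idx[J] == grid.group_idx[i]
    far = np.abs(grid.pos[J] - grid.pos[i]) >= min_cm_same_group
    return J[~same | far]


def _epistatic_pg(engine: ScanEngine, y: np.ndarray, i: int, j: int, h2: float) -> float:
    """Drop-one partial R2_adj/h2 of the interaction block, in percent."""
    tss = float(np.sum((y - y.mean()) ** 2))

    def r2adj(with_inter: bool) -> float:
        rss, k = 0.0, engine.P - 1
        for p, idx in enumerate(engine.fam_idx):
            C = engine.fam_counts[p]
            x1, x2 = C[:, i], C[:, j]
            cols = [np.ones(idx.size), x1, x2]
            if with_inter:
                cols.append((x1 - x1.mean()) * (x2 - x2.mean()))
            Q = _basis(cols)
            k += Q.shape[1] - 1
            rp = y[idx] - Q @ (Q.T @ y[idx])
            rss += float(rp @ rp)
        r2 = 1.0 - rss / tss
        return 1.0 - (1.0 - r2) * (engine.n - 1) / (engine.n - k - 1)

    return max(100.0 * (r2adj(True) - r2adj(False)) / h2, 0.0)


def epistasis_scan(
    engine: ScanEngine,
    y: np.ndarray,
    threshold: float,
    h2: float | None = None,
    min_cm_same_group: float = 20.0,
    cluster_cm: float = 10.0,
) -> list[EpistasisRecord]:
    """Full pairwise interaction scan over the engine's grid.

    Pairs on different groups, and same-group pairs at least
    ``min_cm_same_group`` apart (a linked-pair collinearity guard), are
    tested; significant pairs with both loci within ``cluster_cm`` of each
    other are clustered and the best pair per cluster is reported.  Use an
    engine built on a coarse grid (e.g. 5 cM) for tractability.
    """
    y = np.asarray(y, dtype=float)
    grid = engine.grid
    hits: list[tuple[float, int, int]] = []
    for i in range(grid.n_positions):
        J = _candidates(engine, i, min_cm_same_group)
        if J.size == 0:
            continue
        P = _pair_block(engine, y, i, J)
        for jj in np.flatnonzero(P < threshold):
            hits.append((float(P[jj]), i, int(J[jj])))
    if not hits:
        return []
    # transitive clustering of significant pairs
    parent = list(range(len(hits)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def near(a: int, b: int) -> bool:
        return grid.group_idx[a] == grid.group_idx[b] and abs(
            grid.pos[a] - grid.pos[b]
        ) <= cluster_cm

    for u in range(len(hits)):
        for v in range(u + 1, len(hits)):
            _, i1, j1 = hits[u]
            _, i2, j2 = hits[v]
            if (near(i1, i2) and near(j1, j2)) or (near(i1, j2) and near(j1, i2)):
                parent[find(u)] = find(v)
    best: dict[int, tuple[float, int, int]] = {}
    for u, hit in enumerate(hits):
        root = find(u)
        if root not in best or hit[0] < best[root][0]:
            best[root] = hit
    records = []
    for pval, i, j in sorted(best.values()):
        _, effects = pair_test(engine, y, i, j)
        rec = EpistasisRecord(
            locus1=(grid.groups[grid.group_idx[i]], float(grid.pos[i])),
            locus2=(grid.groups[grid.group_idx[j]], float(grid.pos[j])),
            p_value=pval,
            effects=effects,
            pG_epi=_epistatic_pg(engine, y, i, j, h2) if h2 is not None else float("nan"),
        )
        records.append(rec)
    records.sort(key=lambda r: (r.locus1, r.locus2))
    return records


def landscape(
    engine: ScanEngine, y: np.ndarray, group_a: str, group_b: str, threshold: float
) -> Landscape:
    """-log10(P) surface of all pairwise interactions for one group pair."""
    y = np.asarray(y, dtype=float)
    grid = engine.grid
    sa, sb = grid.group_slices[group_a], grid.group_slices[group_b]
    cols_b = np.arange(sb.start, sb.stop)
    mat = np.empty((sa.stop - sa.start, cols_b.size))
    for row, i in enumerate(range(sa.start, sa.stop)):
        P = _pair_block(engine, y, i, cols_b)
        mat[row] = -np.log10(np.maximum(P, 1e-300))
    return Landscape(
        group_a=group_a,
        group_b=group_b,
        pos_a=grid.pos[sa].copy(),
        pos_b=grid.pos[sb].copy(),
        neglog10p=mat,
        significant=mat > -np.log10(threshold),
        threshold=threshold,
    )
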