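"""Disconnected multiple-line cross QTL scan.

The model for N lines from P families at a tested locus q is

    Y = J M + X_c B_c + X_q B_q + eps

where J is the N x P family-indicator matrix, M the family means, X_q the
N x P matrix of expected allele counts (the column for family p is zero
outside family p), B_q the family-specific allele-substitution effects, and
X_c/B_c analogous blocks for the selected cofactor markers.  The presence
of a QTL is tested with a Gaussian likelihood ratio against the same model
without the X_q B_q block:

    LR = N * ln(RSS0 / RSS1),      LOD = LR / (2 ln 10).

Because every design column is supported on exactly one family, the pooled
OLS fit decomposes into independent per-family regressions whose residual
sums of squares add up.  All scan statistics are therefore computed with
per-family orthonormal bases and rank-one (Frisch-Waugh) updates, which
makes cofactor re-selection inside every permutation replicate affordable.

Cofactors are selected by forward search on the Schwarz information
criterion and are excluded from the model when they lie within 10 cM of
the tested position.  Genome-wide LOD thresholds come from permutations of
Y within family; support intervals use a LOD fall-off of 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .core import DHPopulation, ParameterError
from .genoprob import ExpectedCounts, ScanGrid

log = logging.getLogger(__name__)

__all__ = [
    "ScanResult",
    "QTLRecord",
    "PermutationResult",
    "ScanEngine",
    "declare_qtl",
    "classify_overlap",
]

_LOD_SCALE = 2.0 * np.log(10.0)


@dataclass
class ScanResult:
    """LOD profile and per-family effect estimates over the scan grid."""

    grid: ScanGrid
    lod: np.ndarray  # n_positions
    effects: np.ndarray  # n_positions x P, allele-substitution effects
    cofactors: tuple[int, ...]  # global marker indices used as cofactors


@dataclass
class QTLRecord:
    """A declared QTL: peak, 1-LOD support interval, effects and p_G share."""

    group: str
    peak_pos_cM: float
    support_lo: float
    support_hi: float
    lod: float
    effects: np.ndarray
    pG_single: float = float("nan")  # percent of genotypic variance
    stage: str | None = None


@dataclass
class PermutationResult:
    max_lods: np.ndarray
    alpha: float
    threshold: float
    n_perm: int

    def threshold_at(self, alpha: float) -> float:
        if not 0.0 < alpha <= 1.0:
            raise ParameterError("alpha must lie in (0, 1]")
        return float(np.quantile(self.max_lods, 1.0 - alpha))  # type-7 interpolation


def _basis(cols: list[np.ndarray]) -> np.ndarray:
    """Orthonormal basis of the column span; rank-deficient columns dropped."""
    X = np.column_stack(cols)
    q, r, _ = sla.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    rank = int(np.sum(d > max(X.shape) * np.finfo(float).eps * (d[0] if d.size else 1.0)))
    return q[:, :rank]


def _reductions(C: np.ndarray, Q: np.ndarray, r: np.ndarray):
    """RSS reduction and coefficient for adding each column of C (rank-one).

    Returns (reduction, coefficient, informative) per column; a column in
    the span of Q (e.g. a within-family monomorphic locus) is flagged
    non-informative and contributes nothing.
    """
    Cp = C - Q @ (Q.T @ C)
    raw = np.einsum("ij,ij->j", C, C)
    n2 = np.einsum("ij,ij->j", Cp, Cp)
    ok = n2 > 1e-9 * (raw + 1.0)
    safe = np.where(ok, n2, 1.0)
    proj = Cp.T @ r
    coef = np.where(ok, proj / safe, 0.0)
    red = np.where(ok, proj * proj / safe, 0.0)
    return red, coef, ok


class ScanEngine:
    """Precomputed per-family design blocks for one population and grid.

    One engine is built per (population, grid, expected counts) and reused
    across permutation replicates and cross-validation folds drawn from the
    same matrices.
    """

    def __init__(self, pop: DHPopulation, counts: ExpectedCounts):
        self.pop = pop
        self.grid = counts.grid
        self.counts = counts.counts
        self.fam_idx = pop.family_indices
        self.n = pop.n_lines
        self.P = len(pop.families)
        self.fam_counts = [np.ascontiguousarray(self.counts[idx]) for idx in self.fam_idx]
        self.marker_cols = self.grid.marker_cols
        self.fam_marker = [fc[:, self.marker_cols] for fc in self.fam_counts]
        self.marker_group = pop.gmap.marker_group
        self.marker_pos = pop.gmap.marker_pos

    # -- cofactor selection ---------------------------------------------------

    def select_cofactors(self, y: np.ndarray, max_cofactors: int = 10) -> tuple[int, ...]:
        """Forward selection of cofactor markers under the Schwarz criterion.

        Each marker enters as its family-specific block (one expected-count
        column per family in which it segregates).  Selection starts from
        the family-means model and stops when the criterion no longer
        improves or ``max_cofactors`` is reached.
        """
        y = np.asarray(y, dtype=float)
        n, P = self.n, self.P
        if max_cofactors < 0:
            raise ParameterError("max_cofactors must be >= 0")
        if n <= P * (1 + max_cofactors):
            raise ParameterError("not enough lines for the requested number of cofactors")
        if max_cofactors == 0:
            return ()
        logN = np.log(n)
        Qs, rs, rss = [], [], 0.0
        for p, idx in enumerate(self.fam_idx):
            yp = y[idx]
            Q = np.full((idx.size, 1), 1.0 / np.sqrt(idx.size))
            rp = yp - Q @ (Q.T @ yp)
            Qs.append(Q)
            rs.append(rp)
            rss += float(rp @ rp)
        k = P
        sbc = n * np.log(rss / n) + k * logN
        chosen: list[int] = []
        m = self.marker_cols.size
        taken = np.zeros(m, dtype=bool)
        while len(chosen) < max_cofactors:
            red_tot = np.zeros(m)
            k_m = np.zeros(m, dtype=int)
            per_fam = []
            for p in range(P):
                red, coef, ok = _reductions(self.fam_marker[p], Qs[p], rs[p])
                red_tot += red
                k_m += ok
                per_fam.append((red, coef, ok))
            rss_new = np.maximum(rss - red_tot, 1e-300)
            sbc_new = n * np.log(rss_new / n) + (k + k_m) * logN
            sbc_new[taken | (k_m == 0)] = np.inf
            best = int(np.argmin(sbc_new))
            if not np.isfinite(sbc_new[best]) or sbc_new[best] >= sbc - 1e-9:
                break
            for p in range(P):
                _, _, ok = per_fam[p]
                if not ok[best]:
                    continue
                c = self.fam_marker[p][:, best]
                cp = c - Qs[p] @ (Qs[p].T @ c)
                cp = cp - Qs[p] @ (Qs[p].T @ cp)  # second pass for stability
                qnew = cp / np.linalg.norm(cp)
                beta = float(qnew @ rs[p])
                rs[p] = rs[p] - beta * qnew
                Qs[p] = np.column_stack([Qs[p], qnew])
            rss = float(sum(r @ r for r in rs))
            k += int(k_m[best])
            sbc = float(sbc_new[best])
            taken[best] = True
            chosen.append(best)
        return tuple(sorted(chosen))

    # -- bases with cofactor exclusion ---------------------------------------

    def _bases(self, y, kept: tuple[int, ...], cache: dict):
        """(Q, residual, RSS) per family for the family-means + kept-cofactor model."""
        if kept in cache:
            return cache[kept]
        out = []
        for p, idx in enumerate(self.fam_idx):
            yp = y[idx]
            cols = [np.ones(idx.size)]
            if kept:
                cols.append(self.fam_marker[p][:, list(kept)])
            Q = _basis(cols)
            rp = yp - Q @ (Q.T @ yp)
            out.append((Q, rp, float(rp @ rp)))
        cache[kept] = out
        return out

    # -- genome scan -----------------------------------------------------------

    def scan(
        self,
        y: np.ndarray,
        cofactors: tuple[int, ...] = (),
        exclusion_cm: float = 10.0,
    ) -> ScanResult:
        """LOD profile over the whole grid with per-position cofactor exclusion.

        A cofactor is dropped from the model wherever it lies within
        ``exclusion_cm`` (strictly) of the tested position on the same
        group.  With no cofactors this is plain interval mapping.
        """
        y = np.asarray(y, dtype=float)
        grid = self.grid
        n = self.n
        lod = np.zeros(grid.n_positions)
        effects = np.zeros((grid.n_positions, self.P))
        cof = tuple(cofactors)
        cof_group = self.marker_group[list(cof)] if cof else np.empty(0, dtype=int)
        cof_pos = self.marker_pos[list(cof)] if cof else np.empty(0)
        cache: dict = {}
        for gi in range(len(grid.groups)):
            gsl = grid.group_slices[grid.groups[gi]]
            gpos = grid.pos[gsl]
            local = np.flatnonzero(cof_group == gi)
            # excluded-cofactor pattern per position -> positions sharing a base model
            if local.size:
                excl = np.abs(gpos[:, None] - cof_pos[local][None, :]) < exclusion_cm
                keys = [tuple(np.flatnonzero(row)) for row in excl]
            else:
                keys = [()] * gpos.size
            groups_by_key: dict[tuple, list[int]] = {}
            for j, key in enumerate(keys):
                groups_by_key.setdefault(key, []).append(j)
            for key, js in groups_by_key.items():
                kept = tuple(c for li, c in enumerate(cof) if not (
                    li in set(local[list(key)])
                ))
                bases = self._bases(y, kept, cache)
                cols = np.asarray(js, dtype=np.intp) + gsl.start
                rss0 = sum(b[2] for b in bases)
                red_tot = np.zeros(len(js))
                for p in range(self.P):
                    Q, rp, _ = bases[p]
                    C = self.fam_counts[p][:, cols]
                    red, coef, ok = _reductions(C, Q, rp)
                    red_tot += red
                    effects[cols, p] = coef
                rss1 = np.maximum(rss0 - red_tot, 1e-12 * rss0)
                if np.any(rss0 - red_tot <= 1e-12 * rss0):
                    log.warning("saturated fit at some positions; LOD capped")
                lod[cols] = (n / 2.0) * np.log10(rss0 / rss1)
        return ScanResult(grid=grid, lod=lod, effects=effects, cofactors=cof)

    def position_test(
        self,
        y: np.ndarray,
        grid_col: int,
        cofactors: tuple[int, ...] = (),
        exclusion_cm: float = 10.0,
    ) -> tuple[float, np.ndarray]:
        """LR test of a single position: returns (LOD, per-family effects).

        Cofactors within ``exclusion_cm`` of the position (same group) are
        excluded; families whose count column is constant are dropped from
        the tested block.
        """
        y = np.asarray(y, dtype=float)
        gi = self.grid.group_idx[grid_col]
        t = self.grid.pos[grid_col]
        kept = tuple(
            c
            for c in cofactors
            if not (self.marker_group[c] == gi and abs(self.marker_pos[c] - t) < exclusion_cm)
        )
        bases = self._bases(y, kept, {})
        rss0 = sum(b[2] for b in bases)
        red_tot = 0.0
        eff = np.zeros(self.P)
        for p in range(self.P):
            Q, rp, _ = bases[p]
            C = self.fam_counts[p][:, [grid_col]]
            red, coef, ok = _reductions(C, Q, rp)
            red_tot += float(red[0])
            eff[p] = coef[0]
        rss1 = max(rss0 - red_tot, 1e-12 * rss0)
        return float((self.n / 2.0) * np.log10(rss0 / rss1)), eff

    # -- permutation threshold -------------------------------------------------

    def permutation_threshold(
        self,
        y: np.ndarray,
        n_perm: int = 200,
        alpha: float = 0.10,
        seed: int = 0,
        max_cofactors: int = 10,
        reselect_cofactors: bool = True,
        exclusion_cm: float = 10.0,
    ) -> PermutationResult:
        """Genome-wide LOD threshold from within-family permutations of Y.

        Each replicate permutes the phenotype within every family (the
        family structure is preserved), re-selects cofactors on the permuted
        phenotype, runs the full scan and records the maximum LOD; the
        threshold is the empirical (1 - alpha) quantile.
        """
        if n_perm < 100:
            raise ParameterError("n_perm must be >= 100 for a usable tail quantile")
        if not 0.0 < alpha <= 1.0:
            raise ParameterError("alpha must lie in (0, 1]")
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(seed)
        fixed_cof = None
        if not reselect_cofactors:
            fixed_cof = self.select_cofactors(y, max_cofactors)
        max_lods = np.empty(n_perm)
        for b in range(n_perm):
            yp = y.copy()
            for idx in self.fam_idx:
                yp[idx] = yp[idx][rng.permutation(idx.size)]
            cof = self.select_cofactors(yp, max_cofactors) if fixed_cof is None else fixed_cof
            res = self.scan(yp, cof, exclusion_cm)
            max_lods[b] = float(res.lod.max())
        thr = float(np.quantile(max_lods, 1.0 - alpha))
        return PermutationResult(max_lods=max_lods, alpha=alpha, threshold=thr, n_perm=n_perm)

    # -- explained genotypic variance -------------------------------------------

    def _multi_qtl_rss(self, y: np.ndarray, grid_cols: list[int]) -> tuple[float, int]:
        """Pooled RSS and non-intercept parameter count of the simultaneous model
        family means + all QTL blocks."""
        rss = 0.0
        k = self.P - 1  # family means beyond one grand intercept
        for p, idx in enumerate(self.fam_idx):
            yp = y[idx]
            cols = [np.ones(idx.size)]
            if grid_cols:
                cols.append(self.fam_counts[p][:, grid_cols])
            Q = _basis(cols)
            k += Q.shape[1] - 1  # segregating QTL columns in this family
            rp = yp - Q @ (Q.T @ yp)
            rss += float(rp @ rp)
        return rss, k

    def proportion_genotypic_variance(
        self, qtl: list[QTLRecord], y: np.ndarray, h2: float
    ) -> tuple[float, list[float]]:
        """p_G = 100 * R2_adj / h2 for the simultaneous multi-QTL model.

        R2 is taken against the grand-mean baseline with the family means in
        the model; R2_adj = 1 - (1 - R2)(N - 1)/(N - k - 1) with k the
        number of fitted non-intercept parameters.  Per-QTL shares are
        drop-one partials, floored at 0.
        """
        if not 0.0 < h2 <= 1.0:
            raise ParameterError("h2 must lie in (0, 1]")
        if not qtl:
            raise ParameterError("QTL set is empty")
        y = np.asarray(y, dtype=float)
        cols = [self.grid.locate(q.group, q.peak_pos_cM) for q in qtl]
        tss = float(np.sum((y - y.mean()) ** 2))

        def pg(use: list[int]) -> float:
            rss, k = self._multi_qtl_rss(y, use)
            if self.n <= k + 1:
                raise ParameterError("model over-parameterized: N <= k + 1")
            r2 = 1.0 - rss / tss
            r2a = 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - k - 1)
            return 100.0 * r2a / h2

        combined = pg(cols)
        singles = [
            max(combined - pg([c for j, c in enumerate(cols) if j != i]), 0.0)
            if len(cols) > 1
            else max(combined, 0.0)
            for i in range(len(cols))
        ]
        return combined, singles


# -- QTL declaration and cross-stage classification ----------------------------


def declare_qtl(
    result: ScanResult,
    threshold: float,
    fall_off: float = 1.0,
    merge_distance_cm: float = 20.0,
    stage: str | None = None,
) -> list[QTLRecord]:
    """Declare QTL from a LOD profile.

    Per group, local maxima above the threshold are candidate peaks.  Two
    peaks on one group are distinct QTL only if they are more than
    ``merge_distance_cm`` apart and separated by a valley at least
    ``fall_off`` LOD below the lower peak; otherwise the lower peak is
    merged into the higher.  The support interval extends from the peak to
    the outermost contiguous positions with LOD >= peak - ``fall_off``.
    """
    grid = result.grid
    records: list[QTLRecord] = []
    for g in grid.groups:
        sl = grid.group_slices[g]
        l = result.lod[sl]
        pos = grid.pos[sl]
        m = l.size
        cand = [
            j
            for j in range(m)
            if l[j] >= threshold
            and (j == 0 or l[j] >= l[j - 1])
            and (j == m - 1 or l[j] >= l[j + 1])
        ]
        cand.sort(key=lambda j: -l[j])
        accepted: list[int] = []
        for j in cand:
            distinct = True
            for a in accepted:
                lo, hi = min(j, a), max(j, a)
                if abs(pos[j] - pos[a]) <= merge_distance_cm:
                    distinct = False
                    break
                valley = l[lo : hi + 1].min()
                if valley > min(l[j], l[a]) - fall_off:
                    distinct = False
                    break
            if distinct:
                accepted.append(j)
        for j in sorted(accepted):
            lim = l[j] - fall_off
            lo = j
            while lo > 0 and l[lo - 1] >= lim:
                lo -= 1
            hi = j
            while hi < m - 1 and l[hi + 1] >= lim:
                hi += 1
            records.append(
                QTLRecord(
                    group=g,
                    peak_pos_cM=float(pos[j]),
                    support_lo=float(pos[lo]),
                    support_hi=float(pos[hi]),
                    lod=float(l[j]),
                    effects=result.effects[sl.start + j].copy(),
                    stage=stage,
                )
            )
    return records


def classify_overlap(
    qtl_by_stage: dict[str, list[QTLRecord]], window_cm: float = 10.0
) -> tuple[dict[tuple[str, ...], int], list[list[tuple[str, QTLRecord]]]]:
    """Cross-stage overlap classification (the Venn counts).

    Two QTL overlap iff they lie on the same group within ``window_cm``
    (boundary inclusive); overlap is transitively closed into clusters.
    Returns counts per stage-set (sorted stage tuples) and the clusters.
    """
    items = [(s, q) for s, qs in qtl_by_stage.items() for q in qs]
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            qi, qj = items[i][1], items[j][1]
            if qi.group == qj.group and abs(qi.peak_pos_cM - qj.peak_pos_cM) <= window_cm:
                parent[find(i)] = find(j)
    clusters: dict[int, list[tuple[str, QTLRecord]]] = {}
    for i, it in enumerate(items):
        clusters.setdefault(find(i), []).append(it)
    counts: dict[tuple[str, ...], int] = {}
    ordered_stages = list(qtl_by_stage)
    for members in clusters.values():
        key = tuple(s for s in ordered_stages if any(m[0] == s for m in members))
        counts[key] = counts.get(key, 0) + 1
    return counts, list(clusters.values())
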