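"""Expected allele counts at arbitrary scan positions for DH lines.

At a tested position q between two genotyped markers, the genotype of a DH
line is not observed; the scan model uses its conditional expectation given
the flanking marker genotypes.  Along one chromatid the parental origin is
a two-state Markov chain under no interference, so conditioning on the
nearest informative flanking markers is exact.  Distances are converted to
recombination fractions with the Haldane mapping function.

Counts are on the 0..2 scale (parent-A allele count of the doubled line):
``2 * P(A at q | flanks)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .core import DHPopulation, GeneticMap, ParameterError

__all__ = ["haldane_r", "dh_prob", "ScanGrid", "make_grid", "ExpectedCounts", "expected_counts"]


def haldane_r(d_cM):
    """Haldane recombination fraction r = 0.5*(1 - exp(-2d/100)) for d in cM."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ParameterError("map distance must be >= 0")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d_cM) else r


def dh_prob(left_allele, right_allele, r_left: float, r_right: float) -> float:
    """P(parent-A allele at a position | flanking alleles) for one DH line.

    Alleles are 'A', 'B' or None (missing flank).  With both flanks observed
    the two-state Markov chain gives
    P(A | aL, aR) = t(aL->A; rL) * t(A->aR; rR) / sum over the two states,
    with t(same) = 1 - r.  One observed flank conditions one-sidedly; none
    observed gives the uninformative 0.5.
    """
    for r in (r_left, r_right):
        if not 0.0 <= r <= 0.5:
            raise ParameterError("recombination fraction must lie in [0, 0.5]")
    aL = None if left_allele in (None, "missing") else left_allele
    aR = None if right_allele in (None, "missing") else right_allele
    if aL is None and aR is None:
        return 0.5
    if aR is None:
        return 1.0 - r_left if aL == "A" else r_left
    if aL is None:
        return 1.0 - r_right if aR == "A" else r_right
    pA = ((1 - r_left) if aL == "A" else r_left) * ((1 - r_right) if aR == "A" else r_right)
    pB = (r_left if aL == "A" else (1 - r_left)) * (r_right if aR == "A" else (1 - r_right))
    return pA / (pA + pB)


@dataclass(frozen=True)
class ScanGrid:
    """Ordered test positions (group, pos_cM) covering every linkage group.

    Contains every marker position plus a regular step grid, so counts at
    marker loci reproduce observed genotypes and profiles are continuous.
    """

    groups: tuple[str, ...]
    pos: np.ndarray  # cM per grid position
    group_idx: np.ndarray  # int index into groups per position
    step_cm: float
    marker_cols: np.ndarray  # grid column of each map marker (global marker order)

    @property
    def n_positions(self) -> int:
        return len(self.pos)

    @cached_property
    def group_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        for gi, g in enumerate(self.groups):
            idx = np.flatnonzero(self.group_idx == gi)
            out[g] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def locate(self, group: str, pos_cM: float) -> int:
        """Grid column of the position closest to (group, pos_cM)."""
        sl = self.group_slices[group]
        return sl.start + int(np.argmin(np.abs(self.pos[sl] - pos_cM)))


def make_grid(gmap: GeneticMap, step_cm: float = 1.0) -> ScanGrid:
    """Build the scan grid: marker positions united with a ``step_cm`` lattice."""
    if step_cm <= 0:
        raise ParameterError("step_cm must be > 0")
    pos_parts: list[np.ndarray] = []
    gidx_parts: list[np.ndarray] = []
    marker_cols = np.empty(gmap.n_markers, dtype=np.intp)
    offset = 0
    for gi, g in enumerate(gmap.groups):
        sl = gmap.group_slices[g]
        mpos = gmap.marker_pos[sl]
        lattice = np.arange(mpos[0], mpos[-1] + 1e-9, step_cm)
        pos = np.unique(np.round(np.concatenate([mpos, lattice]), 6))
        pos_parts.append(pos)
        gidx_parts.append(np.full(pos.size, gi, dtype=np.intp))
        marker_cols[sl] = offset + np.searchsorted(pos, np.round(mpos, 6))
        offset += pos.size
    return ScanGrid(
        groups=gmap.groups,
        pos=np.concatenate(pos_parts),
        group_idx=np.concatenate(gidx_parts),
        step_cm=float(step_cm),
        marker_cols=marker_cols,
    )


@dataclass(frozen=True)
class ExpectedCounts:
    """Line x grid-position matrix of expected parent-A allele counts in [0, 2]."""

    grid: ScanGrid
    counts: np.ndarray

    def at_markers(self, gmap: GeneticMap) -> np.ndarray:
        """Counts restricted to marker loci (missing calls imputed from flanks)."""
        return self.counts[:, self.grid.marker_cols]


def expected_counts(pop: DHPopulation, grid: ScanGrid) -> ExpectedCounts:
    """Expected allele counts for every line at every grid position.

    Uses the nearest non-missing flanking marker on each side within the
    linkage group (exact under the Markov chain when the skipped markers are
    missing).  A line with no genotyped marker on a group gets the
    uninformative count 1.0 there.
    """
    gmap = pop.gmap
    n = pop.n_lines
    out = np.full((n, grid.n_positions), 1.0)
    for gi, g in enumerate(gmap.groups):
        msl = gmap.group_slices[g]
        gsl = grid.group_slices[g]
        mpos = gmap.marker_pos[msl]
        gpos = grid.pos[gsl]
        G = pop.genotypes[:, msl]  # n x m, entries 0/2/NaN
        m = mpos.size
        obs = ~np.isnan(G)
        # per line: index of nearest non-missing marker at-or-before / at-or-after each slot
        ar = np.broadcast_to(np.arange(m), G.shape)
        prev = np.where(obs, ar, -1)
        np.maximum.accumulate(prev, axis=1, out=prev)
        nxt = np.where(obs, ar, m)
        nxt = np.flip(np.minimum.accumulate(np.flip(nxt, axis=1), axis=1), axis=1)
        isA = G == 2.0  # defined only where obs
        for j, t in enumerate(gpos):
            il = int(np.searchsorted(mpos, t + 1e-9) - 1)  # last marker slot at/before t
            ir = int(np.searchsorted(mpos, t - 1e-9))  # first marker slot at/after t
            L = prev[:, il] if il >= 0 else np.full(n, -1, dtype=np.intp)
            R = nxt[:, ir] if ir < m else np.full(n, m, dtype=np.intp)
            hasL = L >= 0
            hasR = R < m
            Ls = np.where(hasL, L, 0)
            Rs = np.where(hasR, R, m - 1)
            rl = haldane_r(np.where(hasL, t - mpos[Ls], 0.0))
            rr = haldane_r(np.where(hasR, mpos[Rs] - t, 0.0))
            aL = np.take_along_axis(isA, Ls[:, None], axis=1)[:, 0]
            aR = np.take_along_axis(isA, Rs[:, None], axis=1)[:, 0]
            # two-sided Markov conditioning; degrade gracefully where a flank is absent
            pl_A = np.where(hasL, np.where(aL, 1 - rl, rl), 1.0)
            pl_B = np.where(hasL, np.where(aL, rl, 1 - rl), 1.0)
            pr_A = np.where(hasR, np.where(aR, 1 - rr, rr), 1.0)
            pr_B = np.where(hasR, np.where(aR, rr, 1 - rr), 1.0)
            num = pl_A * pr_A
            den = num + pl_B * pr_B
            pA = np.where(hasL | hasR, num / den, 0.5)
            out[:, gsl.start + j] = 2.0 * pA
    return ExpectedCounts(grid=grid, counts=out)
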