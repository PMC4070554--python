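"""Core domain containers shared across the pipeline.

A genetic map fixes the coordinate system (linkage group, position in cM)
for every scan; a DH population couples that map with a family-structured
genotype matrix.  Doubled-haploid (DH) lines are fully homozygous, so a
genotype is coded as the count of parent-A alleles: 0, 2, or missing (NaN).
Which parent is "A" is defined per family by the family's parent pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["GeneticMap", "FamilySpec", "DHPopulation", "ParameterError", "ValidationError"]


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class ValidationError(ValueError):
    """Input data violate a structural invariant (with location where known)."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions per linkage group.

    Markers are stored in a single global order: grouped by linkage group,
    position-sorted within each group.  Positions are in centimorgans.
    """

    groups: tuple[str, ...]
    marker_ids: tuple[str, ...]
    marker_group: np.ndarray  # int index into ``groups`` per marker
    marker_pos: np.ndarray  # float cM per marker

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(set(self.marker_ids)):
            raise ValidationError("marker ids must be globally unique")
        if len(self.marker_group) != len(self.marker_ids) or len(self.marker_pos) != len(
            self.marker_ids
        ):
            raise ValidationError("marker arrays must have equal length")
        for gi, g in enumerate(self.groups):
            pos = self.marker_pos[self.marker_group == gi]
            if pos.size < 2:
                raise ValidationError(f"linkage group {g!r} has fewer than 2 markers")
            if np.any(np.diff(pos) < 0):
                raise ValidationError(f"positions not sorted within group {g!r}")
            if np.any(pos < 0):
                raise ValidationError(f"negative position in group {g!r}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @cached_property
    def group_slices(self) -> dict[str, slice]:
        """Contiguous slice of the global marker order per group."""
        out: dict[str, slice] = {}
        for gi, g in enumerate(self.groups):
            idx = np.flatnonzero(self.marker_group == gi)
            if idx.size and not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValidationError("markers of one group must be contiguous")
            out[g] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def span(self, group: str) -> tuple[float, float]:
        sl = self.group_slices[group]
        pos = self.marker_pos[sl]
        return float(pos[0]), float(pos[-1])

    @classmethod
    def from_records(cls, records: list[tuple[str, str, float]]) -> "GeneticMap":
        """Build from (group, marker_id, pos_cM) rows; sorts within group."""
        groups: list[str] = []
        for g, _, _ in records:
            if g not in groups:
                groups.append(g)
        rows = sorted(records, key=lambda r: (groups.index(r[0]), r[2]))
        return cls(
            groups=tuple(groups),
            marker_ids=tuple(r[1] for r in rows),
            marker_group=np.array([groups.index(r[0]) for r in rows], dtype=np.intp),
            marker_pos=np.array([r[2] for r in rows], dtype=float),
        )


@dataclass(frozen=True)
class FamilySpec:
    """One biparental DH family: size and parent pair."""

    family_id: str
    n_lines: int
    parent_a_id: str
    parent_b_id: str

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ParameterError("n_lines must be >= 1")
        if self.parent_a_id == self.parent_b_id:
            raise ParameterError("parents of a family must be distinct")


@dataclass
class DHPopulation:
    """Family-structured DH genotype matrix on a genetic map.

    ``genotypes`` is line x marker with entries in {0.0, 2.0, NaN}; NaN marks
    a missing call.  ``latent_loci`` optionally carries simulated true
    genotypes at loci that are not on the marker map (the planted QTL of the
    synthetic generator); real data never have it.
    """

    gmap: GeneticMap
    families: tuple[FamilySpec, ...]
    genotypes: np.ndarray
    line_ids: tuple[str, ...]
    line_family: np.ndarray  # int index into families per line
    latent_loci: dict[tuple[str, float], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genotypes
        if g.shape != (len(self.line_ids), self.gmap.n_markers):
            raise ValidationError("genotype matrix shape does not match lines x markers")
        bad = ~(np.isnan(g) | (g == 0.0) | (g == 2.0))
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"genotype for line {self.line_ids[i]!r}, marker "
                f"{self.gmap.marker_ids[j]!r} is {g[i, j]!r}; DH calls must be 0, 2 or NA"
            )
        if self.line_family.shape != (len(self.line_ids),):
            raise ValidationError("line_family must assign every line to one family")
        if np.any((self.line_family < 0) | (self.line_family >= len(self.families))):
            raise ValidationError("line_family index out of range")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @cached_property
    def family_indices(self) -> list[np.ndarray]:
        """Line index array per family, in family order."""
        return [np.flatnonzero(self.line_family == p) for p in range(len(self.families))]

    def subset(self, idx: np.ndarray) -> "DHPopulation":
        """Restrict to a line subset (e.g. a cross-validation estimation set)."""
        idx = np.asarray(idx, dtype=np.intp)
        return DHPopulation(
            gmap=self.gmap,
            families=self.families,
            genotypes=self.genotypes[idx],
            line_ids=tuple(self.line_ids[i] for i in idx),
            line_family=self.line_family[idx],
            latent_loci={k: v[idx] for k, v in self.latent_loci.items()},
        )
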