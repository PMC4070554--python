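"""Phenotype statistics: variance components, heritability, BLUEs, stage
correlations and parent-vs-family contrasts.

The trial is treated as a balanced two-way (line x environment) design with
replication.  Under balance the expected-mean-squares solution equals the
REML estimates of the full random model, and per-line means across
environments equal the fixed-genotype BLUEs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ParameterError, ValidationError
from .simpop import PhenotypeSet

log = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "Heritability",
    "variance_components",
    "heritability",
    "compute_blues",
    "stage_correlations",
    "ContrastResult",
    "parent_family_contrast",
    "mode_stats",
]


@dataclass(frozen=True)
class VarianceComponents:
    """sigma2_G, sigma2_GE, sigma2_e in squared trait units (>= 0 after truncation)."""

    sigma2_G: float
    sigma2_GE: float
    sigma2_e: float
    n_env: int
    reps: int


@dataclass(frozen=True)
class Heritability:
    h2: float  # entry-mean basis, in [0, 1]


def _as_cube(values) -> np.ndarray:
    """Coerce input to a lines x env x reps array."""
    if isinstance(values, PhenotypeSet):
        values = values.values
    a = np.asarray(values, dtype=float)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise ValidationError("phenotype table must be lines x environments (x reps)")
    return a


def variance_components(values) -> VarianceComponents:
    """Expected-mean-squares variance components for a balanced two-way design.

    sigma2_e = MS_error; sigma2_GE = (MS_GE - MS_error)/r;
    sigma2_G = (MS_G - MS_GE)/(r*E); negative solutions truncated to 0.
    With a single rep per environment sigma2_e and sigma2_GE are confounded:
    sigma2_e is reported as 0 and MS_GE attributed to sigma2_GE (logged).
    """
    a = _as_cube(values)
    G, E, R = a.shape
    if G < 2 or E < 2:
        raise ValidationError("need >= 2 lines and >= 2 environments")
    if np.isnan(a).any():
        raise ValidationError(
            "unbalanced table (missing cells); variance components require the "
            "balanced design produced by the simulator"
        )
    grand = a.mean()
    cell = a.mean(axis=2)
    line_m = cell.mean(axis=1)
    env_m = cell.mean(axis=0)
    ms_g = E * R * np.sum((line_m - grand) ** 2) / (G - 1)
    ms_ge = (
        R
        * np.sum((cell - line_m[:, None] - env_m[None, :] + grand) ** 2)
        / ((G - 1) * (E - 1))
    )
    if R > 1:
        ms_err = np.sum((a - cell[:, :, None]) ** 2) / (G * E * (R - 1))
        s2e = ms_err
        s2ge = (ms_ge - ms_err) / R
    else:
        log.warning("single rep per environment: sigma2_e confounded with sigma2_GE, reported as 0")
        s2e = 0.0
        s2ge = ms_ge
    s2g = (ms_g - ms_ge) / (R * E)
    for name, v in [("sigma2_G", s2g), ("sigma2_GE", s2ge)]:
        if v < 0:
            log.warning("%s estimate %.4g truncated to 0", name, v)
    return VarianceComponents(
        sigma2_G=max(float(s2g), 0.0),
        sigma2_GE=max(float(s2ge), 0.0),
        sigma2_e=max(float(s2e), 0.0),
        n_env=E,
        reps=R,
    )


def heritability(vc: VarianceComponents) -> Heritability:
    """Entry-mean heritability h2 = s2G / (s2G + s2GE/E + s2e/(E*r))."""
    denom = vc.sigma2_G + vc.sigma2_GE / vc.n_env + vc.sigma2_e / (vc.n_env * vc.reps)
    if denom <= 0:
        raise ParameterError("all variance components are zero; heritability undefined")
    return Heritability(h2=float(vc.sigma2_G / denom))


def compute_blues(values) -> np.ndarray:
    """Entry means (BLUEs under balance with fixed genotype effects).

    Missing cells are averaged over the available cells (count logged); a
    line with no observed cell is reported as NaN with a warning.
    """
    a = _as_cube(values)
    flat = a.reshape(a.shape[0], -1)
    n_miss = int(np.isnan(flat).sum())
    if n_miss:
        log.info("compute_blues: averaging over available cells for %d missing cells", n_miss)
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        means = np.nanmean(flat, axis=1)
    empty = np.isnan(means)
    if empty.any():
        log.warning("compute_blues: %d lines have no observed cell; excluded (NaN)", empty.sum())
    return means


def stage_correlations(blues_by_stage: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix between stage-wise entry means, with P values."""
    stages = list(blues_by_stage)
    r = pd.DataFrame(np.eye(len(stages)), index=stages, columns=stages)
    p = pd.DataFrame(np.zeros((len(stages), len(stages))), index=stages, columns=stages)
    for i, s1 in enumerate(stages):
        for j, s2 in enumerate(stages):
            if j <= i:
                continue
            res = stats.pearsonr(blues_by_stage[s1], blues_by_stage[s2])
            r.loc[s1, s2] = r.loc[s2, s1] = res.statistic
            p.loc[s1, s2] = p.loc[s2, s1] = res.pvalue
    return r, p


@dataclass(frozen=True)
class ContrastResult:
    contrast: float
    t: float
    p_value: float
    significant: bool  # at P < 0.01, the reporting convention used here


def parent_family_contrast(
    family_blues: np.ndarray, parent_a_blue: float, parent_b_blue: float
) -> ContrastResult:
    """Orthogonal contrast family mean vs midparent, parents taken as known.

    A significant deviation of the family mean from the midparent value
    indicates non-additive (epistatic) gene action.
    """
    y = np.asarray(family_blues, dtype=float)
    if y.size < 3:
        raise ParameterError("need >= 3 lines in the family")
    contrast = float(y.mean() - (parent_a_blue + parent_b_blue) / 2.0)
    sd = float(y.std(ddof=1))
    if sd == 0.0:
        log.warning("zero family variance; contrast P undefined")
        return ContrastResult(contrast, np.nan, np.nan, False)
    t = contrast / (sd / np.sqrt(y.size))
    p = 2.0 * stats.t.sf(abs(t), df=y.size - 1)
    return ContrastResult(contrast, float(t), float(p), bool(p < 0.01))


def mode_stats(
    values: np.ndarray, grid_size: int = 512, min_rel_depth: float = 0.05
) -> tuple[int, float]:
    """Count modes of a within-family trait distribution by Gaussian KDE.

    Returns (number of modes, valley depth).  KDE local maxima with height
    >= 15% of the global mode count as distinct modes only when separated
    from every stronger mode by a valley at least ``min_rel_depth`` below
    the lower of the two peaks (suppresses sampling wiggles).  Valley depth
    is 1 minus the deepest valley between the two strongest retained modes
    relative to the lower peak (0 for a unimodal distribution).  Used to
    recognise the unimodal -> bimodal -> attenuated pattern a stage-varying
    major QTL leaves on a family.
    """
    y = np.asarray(values, dtype=float)
    kde = stats.gaussian_kde(y)
    lo, hi = y.min(), y.max()
    pad = 0.1 * (hi - lo)
    xs = np.linspace(lo - pad, hi + pad, grid_size)
    d = kde(xs)
    inner = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    peaks = np.flatnonzero(inner) + 1
    peaks = peaks[d[peaks] >= 0.15 * d.max()]
    accepted: list[int] = []
    for j in sorted(peaks, key=lambda j: -d[j]):
        distinct = True
        for a in accepted:
            lo_i, hi_i = min(j, a), max(j, a)
            valley = d[lo_i : hi_i + 1].min()
            if 1.0 - valley / min(d[j], d[a]) < min_rel_depth:
                distinct = False
                break
        if distinct:
            accepted.append(j)
    if len(accepted) < 2:
        return max(len(accepted), 1), 0.0
    order = sorted(accepted, key=lambda j: -d[j])[:2]
    p1, p2 = sorted(order)
    valley = d[p1 : p2 + 1].min()
    depth = 1.0 - valley / min(d[p1], d[p2])
    return len(accepted), float(depth)
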