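"""Fivefold cross-validation of the QTL scan.

QTL are detected on an estimation set (ES, four fifths of the lines,
stratified within family), the explained genotypic variance p_G is
estimated on the ES and validated on the withheld test set (TS) through
the squared correlation between predicted and observed phenotypes divided
by the heritability.  The relative bias 100*(pG_ES - pG_TS)/pG_ES
quantifies how much the estimation-set figure overstates what the QTL
model actually predicts — the overfitting inherent in declaring and
estimating QTL on the same data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ParameterError
from .genoprob import ExpectedCounts
from .scan import QTLRecord, ScanEngine, declare_qtl

log = logging.getLogger(__name__)

__all__ = ["CVResult", "cv_split", "run_cv", "relative_bias"]


@dataclass
class CVResult:
    n_runs: int
    qtl_per_run: list[list[QTLRecord]]
    pG_ES_runs: np.ndarray  # percent, one per run
    pG_TS_runs: np.ndarray
    pG_ES_mean: float
    pG_TS_mean: float
    relative_bias: float  # percent
    qtl_count_mean: float
    frequency: dict[tuple[str, float], int]  # (group, 10 cM bin start) -> detections

    @property
    def n_detected_total(self) -> int:
        return sum(len(q) for q in self.qtl_per_run)


def relative_bias(pG_ES: float, pG_TS: float) -> float:
    """Relative bias (%) of the estimation-set p_G: 100*(pG_ES - pG_TS)/pG_ES."""
    if pG_ES <= 0:
        raise ParameterError("relative bias undefined for pG_ES <= 0")
    return 100.0 * (pG_ES - pG_TS) / pG_ES


def cv_split(
    line_family: np.ndarray, k: int = 5, seed: int = 0, stratify_by_family: bool = True
) -> list[np.ndarray]:
    """k disjoint folds, stratified within family (each fold holds ~1/k of
    every family, fold sizes within +-1)."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    rng = np.random.default_rng(seed)
    line_family = np.asarray(line_family)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    groups = (
        [np.flatnonzero(line_family == p) for p in np.unique(line_family)]
        if stratify_by_family
        else [np.arange(line_family.size)]
    )
    for idx in groups:
        perm = rng.permutation(idx)
        for i, line in enumerate(perm):
            folds[(i + start) % k].append(int(line))
        start = (start + idx.size) % k  # rotate which folds receive the remainder
    return [np.sort(np.array(f, dtype=np.intp)) for f in folds]


def _sub_engine(engine: ScanEngine, idx: np.ndarray) -> ScanEngine:
    sub = engine.pop.subset(idx)
    return ScanEngine(sub, ExpectedCounts(grid=engine.grid, counts=engine.counts[idx]))


def _fit_predict(
    engine: ScanEngine, y: np.ndarray, es: np.ndarray, ts: np.ndarray, cols: list[int]
) -> np.ndarray:
    """OLS fit of family means + QTL blocks on the ES; prediction for TS lines."""
    yhat = np.empty(ts.size)
    fam = engine.pop.line_family
    for p in range(engine.P):
        es_p = es[fam[es] == p]
        ts_p = np.flatnonzero(fam[ts] == p)
        Xe = np.column_stack([np.ones(es_p.size)] + [engine.counts[es_p, c] for c in cols])
        beta, *_ = np.linalg.lstsq(Xe, y[es_p], rcond=None)
        Xt = np.column_stack(
            [np.ones(ts_p.size)] + [engine.counts[ts[ts_p], c] for c in cols]
        )
        yhat[ts_p] = Xt @ beta
    return yhat


def run_cv(
    engine: ScanEngine,
    y: np.ndarray,
    h2: float,
    threshold: float,
    k: int = 5,
    n_replicates: int = 20,
    seed: int = 0,
    max_cofactors: int = 10,
    exclusion_cm: float = 10.0,
    bin_cm: float = 10.0,
) -> CVResult:
    """Replicated k-fold cross-validation of the full scan.

    Per run: cofactor selection and genome scan on the ES with the fixed
    full-data LOD threshold; p_G(ES) from the simultaneous multi-QTL model;
    prediction of the TS from ES-estimated family means and QTL effects;
    p_G(TS) = 100*r^2(yhat, y_TS)/h2, set to 0 when r < 0 or no QTL was
    declared.  Detection frequencies are accumulated in ``bin_cm`` bins.
    """
    y = np.asarray(y, dtype=float)
    fam = engine.pop.line_family
    qtl_per_run: list[list[QTLRecord]] = []
    pg_es_runs, pg_ts_runs = [], []
    freq: dict[tuple[str, float], int] = {}
    for rep in range(n_replicates):
        folds = cv_split(fam, k=k, seed=seed + rep)
        for fold in folds:
            ts = fold
            es = np.setdiff1d(np.arange(y.size), ts)
            fam_sizes = np.bincount(fam[es], minlength=engine.P)
            if np.any(fam_sizes < 10):
                log.warning("a family has < 10 lines in the estimation set; run continues")
            es_eng = _sub_engine(engine, es)
            cof = es_eng.select_cofactors(y[es], max_cofactors)
            res = es_eng.scan(y[es], cof, exclusion_cm)
            qtl = declare_qtl(res, threshold)
            qtl_per_run.append(qtl)
            for q in qtl:
                key = (q.group, float(np.floor(q.peak_pos_cM / bin_cm) * bin_cm))
                freq[key] = freq.get(key, 0) + 1
            if qtl:
                pg_es, _ = es_eng.proportion_genotypic_variance(qtl, y[es], h2)
                cols = [engine.grid.locate(q.group, q.peak_pos_cM) for q in qtl]
                yhat = _fit_predict(engine, y, es, ts, cols)
                r = np.corrcoef(yhat, y[ts])[0, 1]
                pg_ts = 100.0 * r * r / h2 if r > 0 else 0.0
            else:
                pg_es, pg_ts = 0.0, 0.0
            pg_es_runs.append(pg_es)
            pg_ts_runs.append(pg_ts)
    pg_es_runs = np.array(pg_es_runs)
    pg_ts_runs = np.array(pg_ts_runs)
    es_mean = float(pg_es_runs.mean())
    ts_mean = float(pg_ts_runs.mean())
    bias = relative_bias(es_mean, ts_mean) if es_mean > 0 else float("nan")
    return CVResult(
        n_runs=len(qtl_per_run),
        qtl_per_run=qtl_per_run,
        pG_ES_runs=pg_es_runs,
        pG_TS_runs=pg_ts_runs,
        pG_ES_mean=es_mean,
        pG_TS_mean=ts_mean,
        relative_bias=bias,
        qtl_count_mean=float(np.mean([len(q) for q in qtl_per_run])),
        frequency=freq,
    )
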