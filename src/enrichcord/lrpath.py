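"""Logistic-regression gene-set enrichment (LRpath-style).

For every gene set, membership (y in {0,1}) over the gene universe is
regressed on a transform of per-gene differential-expression significance,
``x = -log(p)`` (natural log):

    logit P(y = 1) = beta0 + beta1 * x

A positive slope means members of the set tend to be more significant than
non-members; the two-sided Wald test on ``beta1`` gives the set's p-value,
and Benjamini-Hochberg adjustment across all fitted sets gives the FDR q.
Unlike the ranked-list engine, this treats genes (not samples) as the
sampling units and needs the full universe of p-values, members and
non-members alike.

The per-gene significance source follows the DEG criterion under study:
``t_p`` for the t-test criterion, ``sam_p`` for SAM, and for the
fold-change criterion an empirical rank-based p of |log2FC| (the FC
criterion ranks genes by fold change, so its significance is the
fold-change ranking itself).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .degs import DEGList, GeneStatistics
from .exceptions import AnalysisError, DataError, ParameterError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

PSource = Literal["t_p", "sam_p", "fc_rank"]
P_FLOOR = 1e-15


@dataclass(frozen=True)
class LrpathSetResult:
    set_id: str
    size: int
    beta0: float
    beta1: float
    slope_se: float
    wald_p: float
    bh_q: float
    direction: str        # "pos" iff beta1 > 0

    def significant(self, fdr_cutoff: float = 0.25) -> bool:
        return self.bh_q < fdr_cutoff


def significance_transform(p_values: Sequence[float]) -> np.ndarray:
    """x = -log(p); exact zeros are floored at 1e-15 with a warning."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise DataError("p-values must lie in [0, 1]")
    if np.any(p == 0.0):
        logger.warning("%d zero p-value(s) floored at %.0e",
                       int((p == 0.0).sum()), P_FLOOR)
        p = np.maximum(p, P_FLOOR)
    return -np.log(p)


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    slope_se: float
    wald_p: float
    separated: bool = False


def fit_logistic(y: Sequence[int], x: Sequence[float]) -> LogisticFit:
    """ML logistic fit of y on x (IRLS, deviance tol 1e-8, <=100 iterations).

    Complete separation (diverging slope) yields a flagged result with NaN
    Wald p; a single-class y or constant x is a data error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size:
        raise ParameterError("y and x must have equal length")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise DataError("y must contain both 0s and 1s")
    if np.ptp(x) == 0.0:
        raise DataError("x is constant")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
    except PerfectSeparationError:
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, separated=True)
    b0, b1 = res.params
    se = float(res.bse[1])
    # a (near-)perfectly separating slope drives the deviance to zero with
    # exploding standard errors; such fits carry no usable Wald test
    if (not np.isfinite(se) or se > 1e4 or abs(b1) > 1e3
            or res.deviance < 1e-6):
        return LogisticFit(float(b0), float(b1), se, np.nan, separated=True)
    z = b1 / se
    return LogisticFit(float(b0), float(b1), se, float(2.0 * sps.norm.sf(abs(z))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _fc_rank_p(stats: GeneStatistics, genes: list[str]) -> np.ndarray:
    """Empirical p from the |log2FC| ranking: rank/n, largest |FC| -> 1/n."""
    fc = stats.table.loc[genes, "log2fc"].abs()
    order = sorted(range(len(genes)), key=lambda i: (-fc.iloc[i], genes[i]))
    p = np.empty(len(genes))
    p[order] = np.arange(1, len(genes) + 1) / len(genes)
    return p


def run_lrpath(stats: GeneStatistics, p_source: PSource,
               sets: GeneSetCollection, *, min_size: int = 5,
               max_size: int = 500, fdr_cutoff: float = 0.25,
               universe: Literal["all", "deg"] = "all",
               deg_list: DEGList | None = None) -> list[LrpathSetResult]:
    """One logistic fit per size-filtered set over the gene universe.

    ``universe="all"`` (default) uses every gene with statistics;
    ``universe="deg"`` restricts y and x to the genes of `deg_list`.
    BH adjustment runs across all successfully fitted sets; separated fits
    are excluded from ranking with a logged reason.
    """
    if universe == "deg":
        if deg_list is None:
            raise ParameterError('universe="deg" requires a deg_list')
        genes = list(deg_list.genes)
    else:
        genes = stats.genes
    if not genes:
        raise AnalysisError("empty gene universe")

    if p_source == "t_p":
        p = stats.table.loc[genes, "t_p"].to_numpy(dtype=float)
    elif p_source == "sam_p":
        p = stats.table.loc[genes, "sam_p"].to_numpy(dtype=float)
    elif p_source == "fc_rank":
        p = _fc_rank_p(stats, genes)
    else:
        raise ParameterError(f"unknown p_source {p_source!r}")
    x = significance_transform(p)
    gene_index = {g: i for i, g in enumerate(genes)}

    fitted: list[tuple[str, int, LogisticFit]] = []
    n_sep = 0
    for gs in sets:
        idx = [gene_index[g] for g in gs.members if g in gene_index]
        size = len(idx)
        if not (min_size <= size <= max_size) or size == len(genes):
            continue
        y = np.zeros(len(genes))
        y[idx] = 1.0
        fit = fit_logistic(y, x)
        if fit.separated or not np.isfinite(fit.wald_p):
            n_sep += 1
            logger.warning("lrpath: set %s excluded (separation/degenerate fit)",
                           gs.set_id)
            continue
        fitted.append((gs.set_id, size, fit))
    if not fitted:
        raise AnalysisError("no gene sets could be fitted")
    if n_sep:
        logger.info("lrpath: %d set(s) dropped for separation", n_sep)

    q = bh_adjust([f.wald_p for _, _, f in fitted])
    results = [
        LrpathSetResult(sid, size, f.beta0, f.beta1, f.slope_se, f.wald_p,
                        float(qi), "pos" if f.beta1 > 0 else "neg")
        for (sid, size, f), qi in zip(fitted, q)
    ]
    results.sort(key=lambda r: (r.bh_q, r.wald_p, r.set_id))
    return results
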