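"""Per-gene A-vs-B statistics and DEG selection under three criteria.

The three selection criteria compared throughout the package are

* **FC** — fold-change ranking behind a non-stringent t-test p filter:
  keep genes with ``t_p < p_cutoff`` and ``|log2FC| > fc_cutoff`` (default 1),
  ranked by ``|log2FC|`` descending;
* **SAM** — the moderated d statistic ``d = (mean_A - mean_B) / (s + s0)``
  with the fudge factor ``s0`` chosen by the coefficient-of-variation rule,
  and a permutation p-value (exhaustive label enumeration for small designs);
* **TTEST** — the pooled-variance two-sided Student t-test, p-values used
  directly without multiple-testing correction.

All orderings break ties lexicographically on the gene id so lists are
reproducible across runs and platforms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError, ParameterError
from .io_formats import ExpressionStudy

logger = logging.getLogger(__name__)

Method = Literal["FC", "SAM", "TTEST"]
_ROW_ORDER = [("FC", 0.01), ("FC", 0.05), ("SAM", 0.01), ("SAM", 0.05),
              ("TTEST", 0.01), ("TTEST", 0.05)]


@dataclass(frozen=True)
class DEGCriterion:
    """One DEG-selection rule: a method, its p cutoff and (for FC) the FC cutoff."""

    method: Method
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("FC", "SAM", "TTEST"):
            raise ParameterError(f"unknown method {self.method!r}")
        if not (0.0 < self.p_cutoff < 1.0):
            raise ParameterError("p_cutoff must be in (0, 1)")
        if self.fc_cutoff <= 0:
            raise ParameterError("fc_cutoff must be > 0")

    @property
    def label(self) -> str:
        if self.method == "FC":
            return f"|log2FC|>{self.fc_cutoff:g} (p<{self.p_cutoff:g})"
        name = "t-test" if self.method == "TTEST" else self.method
        return f"{name} (p<{self.p_cutoff:g})"


@dataclass
class GeneStatistics:
    """Per-gene statistics for one site's A-vs-B contrast.

    ``table`` is indexed by gene id with columns ``t_stat``, ``t_p``,
    ``log2fc``, ``sam_d``, ``sam_p``.
    """

    table: pd.DataFrame
    n_a: int
    n_b: int
    s0: float = 0.0

    def __post_init__(self) -> None:
        for col in ("t_stat", "t_p", "log2fc", "sam_d", "sam_p"):
            if col not in self.table.columns:
                raise DataError(f"GeneStatistics table lacks column {col!r}")
        for col in ("t_p", "sam_p"):
            v = self.table[col].to_numpy()
            if np.any((v < 0) | (v > 1)):
                raise DataError(f"{col} outside [0, 1]")
        if not np.isfinite(self.table["log2fc"].to_numpy()).all():
            raise DataError("log2fc must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class DEGList:
    """Ordered gene ids produced by one criterion, with the ranking metric."""

    criterion: DEGCriterion
    genes: list[str]
    ranking_metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise DataError("DEG list contains duplicate genes")
        if len(self.genes) != len(self.ranking_metric):
            raise DataError("genes and ranking_metric lengths differ")

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _pooled_pieces(a: np.ndarray, b: np.ndarray, axis: int = -1):
    """Mean difference and pooled standard error along `axis` (2D-safe)."""
    na, nb = a.shape[axis], b.shape[axis]
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    ssa = ((a - np.expand_dims(ma, axis)) ** 2).sum(axis=axis)
    ssb = ((b - np.expand_dims(mb, axis)) ** 2).sum(axis=axis)
    sp2 = (ssa + ssb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return ma - mb, se, na + nb - 2


def student_t(values_a: Sequence[float], values_b: Sequence[float]
              ) -> tuple[float, float]:
    """Two-sided pooled-variance Student t-test.

    Degenerate branch: zero pooled variance gives ``(0, 1)`` for equal means
    and ``(+/-inf, 0)`` otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >=2 values")
    num, se, df = _pooled_pieces(a, b)
    if se == 0.0:
        return (0.0, 1.0) if num == 0.0 else (math.copysign(math.inf, num), 0.0)
    t = float(num / se)
    return t, float(2.0 * sps.t.sf(abs(t), df))


def log2_fold_change(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """mean(A) - mean(B); inputs must already be on the log2 scale."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    return float(a.mean() - b.mean())


def sam_statistic(values_a, values_b, s0: float) -> float:
    """d = (mean_A - mean_B) / (s + s0), s the pooled standard error of the t-test."""
    if s0 < 0:
        raise ParameterError("s0 must be >= 0")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs >=2 values")
    num, se, _ = _pooled_pieces(a, b)
    denom = se + s0
    if denom == 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    return float(num / denom)


def choose_s0(all_gene_s: np.ndarray, all_gene_r: np.ndarray,
              n_windows: int = 100) -> float:
    """Pick the fudge factor by coefficient-of-variation minimisation.

    Candidates are 0 plus the 5th..95th percentiles (step 5) of the per-gene
    standard errors ``s``.  For each candidate the genes are split into
    ``n_windows`` s-quantile windows; the candidate minimising the CV of the
    within-window median absolute deviations of ``d = r / (s + s0)`` wins.
    Deterministic; a constant ``s`` vector yields 0.
    """
    s = np.asarray(all_gene_s, dtype=float)
    r = np.asarray(all_gene_r, dtype=float)
    if s.size < 20:
        raise ParameterError("choose_s0 needs >=20 genes")
    if s.size != r.size:
        raise ParameterError("s and r must have equal length")
    if np.ptp(s) == 0.0:
        return 0.0
    candidates = [0.0] + [float(np.percentile(s, q)) for q in range(5, 100, 5)]
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, min(n_windows, s.size))
    best_alpha, best_cv = 0.0, np.inf
    for alpha in candidates:
        d = r / (s + alpha)
        mads = np.array([
            np.median(np.abs(d[w] - np.median(d[w]))) for w in windows if w.size
        ])
        mean = mads.mean()
        cv = np.inf if mean == 0.0 else float(mads.std(ddof=0) / mean)
        if cv < best_cv - 1e-12:
            best_alpha, best_cv = alpha, cv
    return best_alpha


def _sam_d_for_masks(x: np.ndarray, mask_a: np.ndarray, s0: float) -> np.ndarray:
    """d for every column mask of A-assignments. x: (G, n); mask_a: (P, n) in {0,1}."""
    n = x.shape[1]
    na = int(mask_a[0].sum())
    nb = n - na
    m = mask_a.T.astype(float)          # (n, P)
    sa = x @ m                          # (G, P) group-A sums
    sb = x.sum(axis=1, keepdims=True) - sa
    qa = (x ** 2) @ m
    qb = (x ** 2).sum(axis=1, keepdims=True) - qa
    ssa = qa - sa ** 2 / na
    ssb = qb - sb ** 2 / nb
    sp2 = np.maximum(ssa + ssb, 0.0) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    num = sa / na - sb / nb
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / denom
    d[denom == 0.0] = np.where(num[denom == 0.0] == 0.0, 0.0, np.inf)
    return d


def sam_permutation_p(values: np.ndarray, labels: Sequence[str], s0: float,
                      n_perm: int = 1000, seed: int = 0,
                      enumerate_limit: int = 1000) -> np.ndarray:
    """Per-gene permutation p-values for the SAM d statistic.

    When the number of distinct A/B label assignments is at most
    ``enumerate_limit`` (252 for a balanced 5-vs-5 design) all of them are
    enumerated and the exact p ``#{|d*| >= |d|} / #perms`` (identity counted)
    is returned; otherwise ``n_perm`` sampled assignments with the +1
    smoothing ``(1 + #{|d*| >= |d|}) / (1 + n_perm)``.  ``s0`` is held fixed
    across permutations.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or x.shape[1] != labels.size:
        raise ParameterError("values must be (genes x samples) matching labels")
    a_idx = np.flatnonzero(labels == "A")
    b_idx = np.flatnonzero(labels == "B")
    if a_idx.size < 2 or b_idx.size < 2 or a_idx.size + b_idx.size != labels.size:
        raise ParameterError("labels must be A/B with >=2 samples per group")
    n, na = labels.size, a_idx.size
    total = math.comb(n, na)
    if total <= enumerate_limit:
        masks = np.zeros((total, n), dtype=np.int8)
        identity_row = None
        a_set = frozenset(a_idx.tolist())
        for i, combo in enumerate(combinations(range(n), na)):
            masks[i, list(combo)] = 1
            if frozenset(combo) == a_set:
                identity_row = i
        d = _sam_d_for_masks(x, masks, s0)
        d_obs = d[:, identity_row]
        count = (np.abs(d) >= np.abs(d_obs)[:, None]).sum(axis=1)
        return count / total
    if n_perm < 50:
        raise ParameterError("n_perm must be >= 50 in sampling mode")
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=np.int8)
    for i in range(n_perm):
        masks[i, rng.permutation(n)[:na]] = 1
    d_null = _sam_d_for_masks(x, masks, s0)
    obs_mask = np.zeros((1, n), dtype=np.int8)
    obs_mask[0, a_idx] = 1
    d_obs = _sam_d_for_masks(x, obs_mask, s0)[:, 0]
    count = (np.abs(d_null) >= np.abs(d_obs)[:, None] - 1e-12).sum(axis=1)
    return (1.0 + count) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# whole-contrast statistics
# ---------------------------------------------------------------------------

def signal_to_noise(values_a: np.ndarray, values_b: np.ndarray) -> np.ndarray:
    """(mean_A - mean_B) / (sd_A + sd_B), an optional GSEA ranking metric."""
    a, b = np.atleast_2d(values_a), np.atleast_2d(values_b)
    denom = a.std(axis=1, ddof=1) + b.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = (a.mean(axis=1) - b.mean(axis=1)) / denom
    return np.where(denom == 0.0, 0.0, snr)


def compute_gene_statistics(study: ExpressionStudy, *, site: str,
                            platform: str | None = None,
                            genes: Sequence[str] | None = None,
                            s0: float | str = "auto",
                            n_perm: int = 1000, seed: int = 0) -> GeneStatistics:
    """Compute t, p, log2FC, SAM d and SAM permutation p for one site's contrast.

    `genes` restricts the analysis to a common-gene list (the default is the
    study's full gene list).  ``s0="auto"`` applies the CV-minimisation rule.
    """
    if genes is None:
        genes = study.genes
    sub = study.subset_genes(genes)
    cols_a = sub.samples_for(platform=platform, site=site, condition="A")
    cols_b = sub.samples_for(platform=platform, site=site, condition="B")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ParameterError(f"site {site!r}: need >=2 replicates per condition")
    a = sub.values[cols_a].to_numpy(dtype=float)
    b = sub.values[cols_b].to_numpy(dtype=float)

    num, se, df = _pooled_pieces(a, b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    t = np.where(se == 0.0, np.where(num == 0.0, 0.0, np.sign(num) * np.inf), t)
    with np.errstate(invalid="ignore"):
        t_p = 2.0 * sps.t.sf(np.abs(t), df)
    t_p = np.where(np.isinf(t), 0.0, np.where(se == 0.0, 1.0, t_p))

    if s0 == "auto":
        s0_val = choose_s0(se, num)
    else:
        s0_val = float(s0)
        if s0_val < 0:
            raise ParameterError("s0 must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / (se + s0_val)
    d = np.where(se + s0_val == 0.0,
                 np.where(num == 0.0, 0.0, np.sign(num) * np.inf), d)

    labels = np.array(["A"] * len(cols_a) + ["B"] * len(cols_b))
    sam_p = sam_permutation_p(np.hstack([a, b]), labels, s0_val,
                              n_perm=n_perm, seed=seed)

    table = pd.DataFrame(
        {"t_stat": t, "t_p": t_p, "log2fc": num, "sam_d": d, "sam_p": sam_p},
        index=pd.Index(genes, name="gene"),
    )
    return GeneStatistics(table, n_a=len(cols_a), n_b=len(cols_b), s0=s0_val)


def select_degs(stats: GeneStatistics, criterion: DEGCriterion) -> DEGList:
    """Apply one criterion; empty results are valid (logged, not an error)."""
    t = stats.table
    if criterion.method == "FC":
        mask = (t["t_p"] < criterion.p_cutoff) & \
               (t["log2fc"].abs() > criterion.fc_cutoff)
        metric, ascending = t["log2fc"].abs(), False
    elif criterion.method == "SAM":
        mask = t["sam_p"] < criterion.p_cutoff
        metric, ascending = t["sam_d"].abs(), False
    else:  # TTEST
        mask = t["t_p"] < criterion.p_cutoff
        metric, ascending = t["t_p"], True
    sel = pd.DataFrame({"metric": metric[mask].to_numpy(),
                        "gene": list(t.index[mask])})
    sel = sel.sort_values(["metric", "gene"], ascending=[ascending, True],
                          kind="stable")
    if sel.empty:
        logger.info("criterion %s selected no genes", criterion.label)
    return DEGList(criterion, list(sel["gene"]), sel["metric"].to_numpy())


def deg_count_table(deg_lists: dict[tuple, DEGList]) -> pd.DataFrame:
    """Counts per (criterion, cutoff) x (platform, site), fixed row/column order.

    `deg_lists` is keyed by ``(platform, site, method, p_cutoff)``.
    """
    columns = list(dict.fromkeys(
        f"{p}_{s}" for (p, s, _m, _c) in deg_lists.keys()
    ))
    rows, labels = [], []
    for method, cutoff in _ROW_ORDER:
        cells = {}
        for (p, s, m, c), dl in deg_lists.items():
            if m == method and c == cutoff:
                cells[f"{p}_{s}"] = len(dl)
        if cells:
            labels.append(DEGCriterion(method, cutoff).label)
            rows.append([cells.get(col, 0) for col in columns])
    return pd.DataFrame(rows, index=labels, columns=columns)
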