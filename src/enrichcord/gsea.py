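"""Weighted Kolmogorov-Smirnov gene-set enrichment on a pre-ranked DEG list.

Given a DEG list ranked by a signed metric, the running sum for a gene set S
increments by ``|r_j|^w / sum_{hits} |r|^w`` at members ("hits") and
decrements by ``1 / (N - N_hits)`` at non-members; the enrichment score (ES)
is the signed maximum deviation from zero.  Significance comes from a
gene-set permutation null: random same-size member sets, size-wise
normalisation to NES (ES divided by the magnitude of the same-sign null
mean) and a pooled-null FDR q-value, reported separately for positively
("pos") and negatively ("neg") enriched sets.

Because enrichment is run on *pre-ranked DEG lists* rather than on the
expression matrix, the null permutes gene-set membership, not sample labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .degs import DEGList, GeneStatistics
from .exceptions import AnalysisError, ParameterError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Unique genes with a real-valued metric, sorted descending (ties by id)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ParameterError("ranked list has duplicate genes")
        if len(self.genes) != len(self.scores):
            raise ParameterError("genes and scores lengths differ")
        if np.any(np.diff(self.scores) > 0):
            raise ParameterError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GseaSetResult:
    set_id: str
    size: int            # members present in the ranked list
    es: float
    nes: float
    fdr_q: float
    direction: str       # "pos" iff es > 0

    def significant(self, fdr_cutoff: float = 0.25) -> bool:
        return self.fdr_q < fdr_cutoff


def build_ranked_list(deg_list: DEGList, stats: GeneStatistics) -> RankedList:
    """Attach each DEG's signed metric and sort descending.

    FC lists use ``log2fc``; SAM lists ``sam_d``; t-test lists
    ``sign(log2fc) * (-log10 t_p)``.  Ties break lexicographically on id.
    """
    if not deg_list.genes:
        raise ParameterError("DEG list is empty")
    t = stats.table
    missing = [g for g in deg_list.genes if g not in t.index]
    if missing:
        raise AnalysisError(f"metric missing for gene(s): {missing[:5]}")
    sub = t.loc[deg_list.genes]
    method = deg_list.criterion.method
    if method == "FC":
        metric = sub["log2fc"].to_numpy(dtype=float)
    elif method == "SAM":
        metric = sub["sam_d"].to_numpy(dtype=float)
    else:
        p = np.clip(sub["t_p"].to_numpy(dtype=float), 1e-300, 1.0)
        metric = np.sign(sub["log2fc"].to_numpy(dtype=float)) * (-np.log10(p))
    order = sorted(range(len(deg_list.genes)),
                   key=lambda i: (-metric[i], deg_list.genes[i]))
    return RankedList([deg_list.genes[i] for i in order], metric[order])


def _es_from_positions(scores: np.ndarray, hit_pos: np.ndarray,
                       weight_exponent: float) -> tuple[float, int, np.ndarray]:
    n = scores.size
    nh = hit_pos.size
    increments = np.full(n, -1.0 / (n - nh))
    w = np.abs(scores[hit_pos]) ** weight_exponent
    total = w.sum()
    if total == 0.0:          # all hit scores zero: fall back to equal weights
        w = np.ones(nh)
        total = float(nh)
    increments[hit_pos] = w / total
    running = np.cumsum(increments)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx, running


def enrichment_score(ranked: RankedList, members: Iterable[str],
                     weight_exponent: float = 1.0
                     ) -> tuple[float, int, np.ndarray]:
    """ES, position of the extremum, and the full running sum for one set."""
    if weight_exponent < 0:
        raise ParameterError("weight_exponent must be >= 0")
    member_set = set(members)
    hit_pos = np.array([i for i, g in enumerate(ranked.genes) if g in member_set],
                       dtype=int)
    if hit_pos.size == 0:
        raise ParameterError("no gene-set members present in the ranked list")
    if hit_pos.size == len(ranked):
        raise ParameterError("gene set covers the whole ranked list")
    return _es_from_positions(ranked.scores, hit_pos, weight_exponent)


def _es_batch(scores: np.ndarray, hit_matrix: np.ndarray,
              weight_exponent: float) -> np.ndarray:
    """ES for many same-size hit-position sets at once. hit_matrix: (P, k)."""
    n = scores.size
    p, k = hit_matrix.shape
    inc = np.full((p, n), -1.0 / (n - k))
    w = np.abs(scores[hit_matrix]) ** weight_exponent      # (P, k)
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0.0
    if zero.any():
        w[zero] = 1.0
        totals[zero] = k
    rows = np.repeat(np.arange(p), k)
    inc[rows, hit_matrix.ravel()] = (w / totals).ravel()
    running = np.cumsum(inc, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(p), idx]


def gene_set_permutation_null(ranked: RankedList, set_size: int, n_perm: int,
                              weight_exponent: float = 1.0,
                              seed: int = 0) -> np.ndarray:
    """ES of `n_perm` uniformly random member sets of the given size."""
    n = len(ranked)
    if not (1 <= set_size < n):
        raise ParameterError(f"set_size must be in [1, {n - 1}]")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    # row-wise random k-subsets via partial argsort of uniform keys
    keys = rng.random((n_perm, n))
    hits = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
    return _es_batch(ranked.scores, hits, weight_exponent)


def normalize_and_fdr(observed: Mapping[str, float],
                      nulls: Mapping[str, np.ndarray]
                      ) -> dict[str, tuple[float, float]]:
    """Size-normalised NES and pooled-null FDR q per set.

    NES divides each ES (observed or null) by the magnitude of the mean
    same-sign null ES of its set.  The q-value for a positively enriched set
    is ``[fraction of pooled null NES >= NES*] / [fraction of observed
    NES >= NES*]`` (restricted to the non-negative tails), clipped to [0, 1]
    and made monotone non-increasing in |NES| within each sign; mirrored for
    negative sets.  Sets without same-sign null values are excluded.
    """
    nes_obs: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for sid, es in observed.items():
        null = np.asarray(nulls[sid], dtype=float)
        if null.size < 100:
            raise ParameterError(f"set {sid!r} has <100 null scores")
        pos, neg = null[null > 0], null[null < 0]
        mu_pos = pos.mean() if pos.size else np.nan
        mu_neg = np.abs(neg.mean()) if neg.size else np.nan
        mu = mu_pos if es >= 0 else mu_neg
        if not np.isfinite(mu) or mu == 0.0:
            logger.warning("set %s: no same-sign null ES; excluded", sid)
            continue
        nes_obs[sid] = es / mu
        parts = []
        if pos.size and np.isfinite(mu_pos) and mu_pos > 0:
            parts.append(pos / mu_pos)
        if neg.size and np.isfinite(mu_neg) and mu_neg > 0:
            parts.append(neg / mu_neg)
        null_nes_pool.append(np.concatenate(parts) if parts else np.empty(0))
    if not nes_obs:
        return {}
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    obs = np.array(list(nes_obs.values()))
    n_pool_pos = int((pool >= 0).sum())
    n_pool_neg = int((pool <= 0).sum())
    n_obs_pos = int((obs >= 0).sum())
    n_obs_neg = int((obs <= 0).sum())

    raw_q: dict[str, float] = {}
    for sid, nes in nes_obs.items():
        if nes >= 0:
            num = (pool >= nes).sum() / n_pool_pos if n_pool_pos else 0.0
            den = (obs >= nes).sum() / n_obs_pos
        else:
            num = (pool <= nes).sum() / n_pool_neg if n_pool_neg else 0.0
            den = (obs <= nes).sum() / n_obs_neg
        raw_q[sid] = float(np.clip(num / den, 0.0, 1.0))

    # enforce q monotone non-increasing in |NES| within each sign
    out: dict[str, tuple[float, float]] = {sid: (nes_obs[sid], raw_q[sid])
                                           for sid in nes_obs}
    # step-up style: a more extreme set may inherit a *smaller* q attained at
    # a deeper threshold, never the other way round
    for sign in (1, -1):
        ids = [sid for sid in nes_obs
               if (nes_obs[sid] >= 0) == (sign == 1)]
        ids.sort(key=lambda sid: abs(nes_obs[sid]))     # least extreme first
        best = np.inf
        for sid in ids:
            best = min(best, raw_q[sid])
            out[sid] = (nes_obs[sid], best)
    return out


def run_gsea(deg_list: DEGList, stats: GeneStatistics,
             sets: GeneSetCollection, *, weight_exponent: float = 1.0,
             n_perm: int = 1000, min_size: int = 5, max_size: int = 500,
             fdr_cutoff: float = 0.25, seed: int = 0) -> list[GseaSetResult]:
    """Full pre-ranked GSEA over a collection; see the module docstring.

    Sets are filtered to those with ``min_size..max_size`` members present in
    the ranked list.  Null ES vectors are shared between sets of equal
    filtered size (the null depends only on the size), with a per-size seed
    substream derived from `seed`.
    """
    ranked = build_ranked_list(deg_list, stats)
    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.genes)}

    filtered: dict[str, np.ndarray] = {}
    skipped = 0
    for gs in sets:
        pos = np.array(sorted(index[g] for g in gs.members if g in index),
                       dtype=int)
        if min_size <= pos.size <= max_size and pos.size < n:
            filtered[gs.set_id] = pos
        else:
            skipped += 1
    if skipped:
        logger.info("gsea: %d/%d sets outside size window [%d, %d] in-list",
                    skipped, len(sets), min_size, max_size)
    if not filtered:
        raise AnalysisError("no gene sets pass the size filter")

    observed = {sid: _es_from_positions(ranked.scores, pos, weight_exponent)[0]
                for sid, pos in filtered.items()}

    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted({pos.size for pos in filtered.values()}):
        sub_seed = int(np.random.SeedSequence([seed, size]).generate_state(1)[0]
                       ) & 0x7FFFFFFF
        null_by_size[size] = gene_set_permutation_null(
            ranked, size, n_perm, weight_exponent, seed=sub_seed)
    nulls = {sid: null_by_size[pos.size] for sid, pos in filtered.items()}

    scored = normalize_and_fdr(observed, nulls)
    results = [
        GseaSetResult(sid, int(filtered[sid].size), observed[sid],
                      nes, q, "pos" if observed[sid] > 0 else "neg")
        for sid, (nes, q) in scored.items()
    ]
    results.sort(key=lambda r: (r.fdr_q, -abs(r.nes), r.set_id))
    return results
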