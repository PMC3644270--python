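"""Percentage of overlapping terms between FDR-ranked significant-term lists.

Two enrichment runs are compared by ranking their significant terms
(q < 0.25, strict) by FDR ascending, truncating both lists to the shorter
length N, and reporting at every depth i = 1..N

    POG_i = 100 * O_i / T_i,   O_i = |top_i(a) & top_i(b)|,   T_i = i.

For the ranked-list engine, which reports positively and negatively
enriched terms separately, each direction is truncated to its own
direction-wise minimum and the two truncated blocks are concatenated
(pos block first); N is then the combined length.  The terminal value
POG_N summarises a comparison ("all terms meeting the FDR criterion").

Overlap is undirected by default: a term counts as shared regardless of the
direction it was enriched in (a direction-aware mode is available).  An
empty list on either side makes the comparison NA — absence of evidence,
not disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .gsea import GseaSetResult
from .lrpath import LrpathSetResult

logger = logging.getLogger(__name__)

FAMILY_INTER_SITE = "inter_site"
FAMILY_INTRA_SITE = "intra_site_criteria"
FAMILY_INTER_PLATFORM = "inter_platform"
CRITERION_PAIRS = (("FC", "SAM"), ("FC", "TTEST"), ("SAM", "TTEST"))


@dataclass
class SignificantTermList:
    """Ordered significant terms from one enrichment run (one direction)."""

    source: str                     # "gsea" or "lrpath"
    terms: list[str]
    keys: list[tuple]               # per-term (q, secondary score)
    fdr_cutoff: float = 0.25

    def __post_init__(self) -> None:
        if len(self.terms) != len(set(self.terms)):
            raise ParameterError("significant-term list has duplicates")
        if len(self.terms) != len(self.keys):
            raise ParameterError("terms and keys lengths differ")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class ConcordanceCurve:
    """POG_i for i = 1..N between two matched term lists."""

    depths: np.ndarray
    overlaps: np.ndarray            # O_i
    percentages: np.ndarray         # POG_i = 100 * O_i / i

    @property
    def n(self) -> int:
        return int(self.depths[-1]) if self.depths.size else 0

    @property
    def terminal(self) -> float:
        return float(self.percentages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth": self.depths, "overlap": self.overlaps,
                             "pog": self.percentages})


def rank_significant_terms(results: Sequence, fdr_cutoff: float = 0.25):
    """Filter to q < cutoff (strict) and order by FDR ascending.

    Ties break by the secondary score (|NES| descending for the ranked-list
    engine, Wald p ascending for the regression engine), then by set id.
    For GSEA results returns ``(pos_list, neg_list)``; for LRpath one list.
    """
    if results and isinstance(results[0], GseaSetResult):
        out = []
        for direction in ("pos", "neg"):
            rows = [r for r in results
                    if r.direction == direction and r.fdr_q < fdr_cutoff]
            rows.sort(key=lambda r: (r.fdr_q, -abs(r.nes), r.set_id))
            out.append(SignificantTermList(
                "gsea", [r.set_id for r in rows],
                [(r.fdr_q, abs(r.nes)) for r in rows], fdr_cutoff))
        return tuple(out)
    rows = [r for r in results if r.bh_q < fdr_cutoff]
    rows.sort(key=lambda r: (r.bh_q, r.wald_p, r.set_id))
    return SignificantTermList("lrpath", [r.set_id for r in rows],
                               [(r.bh_q, r.wald_p) for r in rows], fdr_cutoff)


def match_lists(a: SignificantTermList, b: SignificantTermList
                ) -> tuple[list[str], list[str], int]:
    """Truncate both lists to the shorter length; N = 0 means NA."""
    if a.source != b.source:
        raise ParameterError("cannot match lists from different engines")
    n = min(len(a), len(b))
    if n == 0:
        logger.info("comparison undefined: at least one empty term list")
        return [], [], 0
    return a.terms[:n], b.terms[:n], n


def combine_pos_neg(pos_a: SignificantTermList, neg_a: SignificantTermList,
                    pos_b: SignificantTermList, neg_b: SignificantTermList
                    ) -> tuple[list[str], list[str], int]:
    """Direction-wise truncation then concatenation (pos block, then neg).

    Each direction is truncated to min(|side a|, |side b|) for that
    direction; N is the summed length.  Both directions empty on either
    side -> NA (N = 0).
    """
    for lst in (pos_a, neg_a, pos_b, neg_b):
        if lst.source != "gsea":
            raise ParameterError("combine_pos_neg expects GSEA lists")
    n_pos = min(len(pos_a), len(pos_b))
    n_neg = min(len(neg_a), len(neg_b))
    if n_pos + n_neg == 0:
        return [], [], 0
    combined_a = pos_a.terms[:n_pos] + neg_a.terms[:n_neg]
    combined_b = pos_b.terms[:n_pos] + neg_b.terms[:n_neg]
    return combined_a, combined_b, n_pos + n_neg


def overlap_percentage(a_trunc: Sequence[str], b_trunc: Sequence[str],
                       depth: int) -> float:
    """100 * |top_i(a) & top_i(b)| / i."""
    n = min(len(a_trunc), len(b_trunc))
    if not (1 <= depth <= n):
        raise ParameterError(f"depth must be in [1, {n}]")
    o = len(set(a_trunc[:depth]) & set(b_trunc[:depth]))
    return 100.0 * o / depth


def concordance_curve(a, b) -> ConcordanceCurve:
    """POG at every depth 1..N for two matched (equal-length-able) lists.

    Accepts plain term sequences or SignificantTermList objects (matched via
    :func:`match_lists`).  N = 0 raises ParameterError (NA upstream).
    """
    if isinstance(a, SignificantTermList):
        a, b, n = match_lists(a, b)
    else:
        n = min(len(a), len(b))
        a, b = list(a[:n]), list(b[:n])
    if n == 0:
        raise ParameterError("cannot build a curve from an empty comparison")
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    overlaps = np.empty(n, dtype=int)
    o = 0
    for i in range(n):
        ta, tb = a[i], b[i]
        if ta == tb:
            o += 1
        else:
            if ta in seen_b:
                o += 1
            if tb in seen_a:
                o += 1
        seen_a.add(ta)
        seen_b.add(tb)
        overlaps[i] = o
    depths = np.arange(1, n + 1)
    return ConcordanceCurve(depths, overlaps, 100.0 * overlaps / depths)


def _terminal(entry_a, entry_b, engine: str):
    """(N, POG_N, curve or None, note) for one catalog pair."""
    if engine == "gsea":
        pos_a, neg_a = entry_a
        pos_b, neg_b = entry_b
        a, b, n = combine_pos_neg(pos_a, neg_a, pos_b, neg_b)
    else:
        a, b, n = match_lists(entry_a, entry_b)
    if n == 0:
        return 0, np.nan, None, "NA: empty significant list"
    curve = concordance_curve(a, b)
    return n, curve.terminal, curve, ""


@dataclass
class ComparisonPlan:
    """Which pairwise comparisons to emit from a results catalog.

    The catalog is keyed by ``(platform, site, method, p_cutoff, engine)``;
    GSEA entries are ``(pos, neg)`` SignificantTermList pairs, LRpath
    entries single lists.
    """

    platforms: list[str]
    sites: list[str]
    criteria: list[tuple[str, float]]       # (method, p_cutoff)
    engines: list[str] = field(default_factory=lambda: ["gsea", "lrpath"])
    families: tuple[str, ...] = (FAMILY_INTER_SITE, FAMILY_INTRA_SITE,
                                 FAMILY_INTER_PLATFORM)

    def pairs(self):
        """Yield (family, engine, key_a, key_b) for every planned comparison."""
        cutoffs = sorted({c for _m, c in self.criteria})
        for engine in self.engines:
            if FAMILY_INTER_SITE in self.families:
                for p in self.platforms:
                    for m, c in self.criteria:
                        for i, sa in enumerate(self.sites):
                            for sb in self.sites[i + 1:]:
                                yield (FAMILY_INTER_SITE, engine,
                                       (p, sa, m, c, engine), (p, sb, m, c, engine))
            if FAMILY_INTRA_SITE in self.families:
                methods = {m for m, _c in self.criteria}
                for p in self.platforms:
                    for s in self.sites:
                        for c in cutoffs:
                            for ma, mb in CRITERION_PAIRS:
                                if {(ma, c), (mb, c)} <= set(self.criteria) \
                                        and {ma, mb} <= methods:
                                    yield (FAMILY_INTRA_SITE, engine,
                                           (p, s, ma, c, engine),
                                           (p, s, mb, c, engine))
            if FAMILY_INTER_PLATFORM in self.families:
                for s in self.sites:
                    for m, c in self.criteria:
                        for i, pa in enumerate(self.platforms):
                            for pb in self.platforms[i + 1:]:
                                yield (FAMILY_INTER_PLATFORM, engine,
                                       (pa, s, m, c, engine), (pb, s, m, c, engine))


def compare_all(catalog: Mapping[tuple, object], plan: ComparisonPlan
                ) -> tuple[pd.DataFrame, dict[int, ConcordanceCurve], list]:
    """Emit every planned pairwise comparison; missing entries are excluded.

    Returns (table, curves keyed by table row position, exclusions).
    """
    rows, curves, exclusions = [], {}, []
    for family, engine, key_a, key_b in plan.pairs():
        if key_a not in catalog or key_b not in catalog:
            missing = [k for k in (key_a, key_b) if k not in catalog]
            exclusions.append({"family": family, "missing": missing})
            continue
        n, pog, curve, note = _terminal(catalog[key_a], catalog[key_b], engine)
        pa, sa, ma, ca, _ = key_a
        pb, sb, mb, cb, _ = key_b
        idx = len(rows)
        rows.append({
            "family": family, "engine": engine,
            "platform_a": pa, "site_a": sa, "method_a": ma, "cutoff_a": ca,
            "platform_b": pb, "site_b": sb, "method_b": mb, "cutoff_b": cb,
            "n": n, "pog_terminal": pog, "note": note,
        })
        if curve is not None:
            curves[idx] = curve
    return pd.DataFrame(rows), curves, exclusions
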