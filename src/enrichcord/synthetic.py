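"""Synthetic multi-platform, multi-site, two-condition expression studies.

The generator emulates the reference-sample design used for microarray
quality-control work: two RNA conditions (A and B) with broad
transcriptome-wide differences, several vendor platforms each measuring its
own probe subset with a recorded common-gene intersection, several
independent test sites per platform, and five replicates per condition per
site.  Everything is additive Gaussian on the log2 scale:

    x_{g,q,s,c,k} = alpha_g + lambda_{g,q} + nu_{g,q,s} + delta_g * 1[c=A] + eps

with gene baseline ``alpha_g ~ N(8, 2^2)``, platform offset
``lambda ~ N(0, platform_sd^2)``, site offset ``nu ~ N(0, site_sd^2)`` and
replicate noise ``eps ~ N(0, sigma_g^2)``, ``sigma_g ~ U(gene_sd_range)``.
A gene is differentially expressed (DE) with probability ``de_fraction``;
DE genes get ``|delta_g| ~ N(effect_size_log2, effect_sd^2)`` truncated at 0.
Gene sets standing in for GO terms are drawn at random; a handful of
"planted" sets multiply their members' DE probability by
``planted_de_enrichment`` (capped at 1) and impose a per-set sign on their
DE members, so both set-level engines have a recoverable, directionally
coherent ground truth.  Non-planted DE genes flip a fair coin for sign.

One global seed expands into fixed per-component substreams, so changing
e.g. the number of gene sets does not reshuffle the noise draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, ParameterError
from .io_formats import ExpressionStudy, GeneSet, GeneSetCollection

# substream keys
_K_SETS, _K_DE, _K_EFFECTS, _K_GENE_PARAMS, _K_COVERAGE, _K_NOISE = range(1, 7)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class StudyDesign:
    """All knobs of the generative model; defaults are the desk-scale study.

    ``n_genes=2000`` stands in for the ~12k common genes of a real
    multi-platform study while keeping the full pipeline fast; the
    3 platforms x 3 sites x 5 replicates layout matches the reference
    design the generator emulates.
    """

    n_genes: int = 2000
    platforms: tuple[str, ...] = ("AFX", "AG1", "ILM")
    sites_per_platform: int = 3
    replicates: int = 5
    de_fraction: float = 0.30
    effect_size_log2: float = 1.5
    effect_sd: float = 0.7
    gene_sd_range: tuple[float, float] = (0.2, 0.8)
    site_sd: float = 0.2
    platform_sd: float = 0.3
    platform_coverage: float = 0.85
    n_sets: int = 150
    set_size_range: tuple[int, int] = (20, 80)
    n_planted_sets: int = 10
    planted_de_enrichment: float = 5.0
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ParameterError("n_genes must be >= 2")
        if self.replicates < 2:
            raise ParameterError("replicates must be >= 2")
        if not self.platforms or self.sites_per_platform < 1:
            raise ParameterError("need >=1 platform and >=1 site")
        if not (0.0 <= self.de_fraction < 1.0):
            raise ParameterError("de_fraction must be in [0, 1)")
        if self.effect_size_log2 <= 0 or self.effect_sd < 0:
            raise ParameterError("effect_size_log2 > 0 and effect_sd >= 0 required")
        lo, hi = self.gene_sd_range
        if not (0 < lo <= hi):
            raise ParameterError("gene_sd_range must satisfy 0 < low <= high")
        if self.site_sd < 0 or self.platform_sd < 0:
            raise ParameterError("site_sd and platform_sd must be >= 0")
        if not (0.0 < self.platform_coverage <= 1.0):
            raise ParameterError("platform_coverage must be in (0, 1]")
        smin, smax = self.set_size_range
        if not (2 <= smin <= smax):
            raise ParameterError("set_size_range must lie within [2, n_genes]")
        if smax > self.n_genes:
            raise ParameterError(
                f"set_size_range max {smax} exceeds n_genes {self.n_genes}"
            )
        if self.n_planted_sets > self.n_sets:
            raise ParameterError("n_planted_sets must be <= n_sets")
        if self.planted_de_enrichment < 1:
            raise ParameterError("planted_de_enrichment must be >= 1")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")

    # Named study conditions -----------------------------------------------
    @classmethod
    def desk_default(cls, seed: int = 0) -> "StudyDesign":
        """The default desk-scale analog of the full three-platform study."""
        return cls(seed=seed)

    @classmethod
    def heteroscedastic_pair(cls, seed: int = 0) -> "StudyDesign":
        """Two platforms x two sites with strongly gene-dependent noise.

        Used for the criterion-comparison study: the wide ``sigma_g`` range
        (0.05..2.0 on the log2 scale) is what separates variance-sensitive
        (t-test) from variance-damped (fold change, SAM) DEG selection.
        """
        return cls(
            n_genes=1500,
            platforms=("P1", "P2"),
            sites_per_platform=2,
            gene_sd_range=(0.05, 2.0),
            site_sd=0.3,
            platform_coverage=0.9,
            n_sets=120,
            seed=seed,
        )

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass(frozen=True)
class GroundTruth:
    """True per-gene effects and the identity of the planted enriched sets."""

    effects: pd.Series            # delta_g (log2 A - B), 0 for non-DE genes
    planted_sets: tuple[str, ...]
    planted_directions: dict[str, int]  # set id -> +1 / -1

    @property
    def de_genes(self) -> list[str]:
        return list(self.effects.index[self.effects != 0.0])


class SyntheticStudy(NamedTuple):
    studies: list[ExpressionStudy]      # one per platform
    gene_sets: GeneSetCollection
    truth: GroundTruth


def generate_gene_sets(design: StudyDesign, rng: np.random.Generator | None = None
                       ) -> GeneSetCollection:
    """Draw ``n_sets`` random gene sets with sizes uniform in ``set_size_range``.

    Members are drawn without replacement within a set; different sets may
    overlap freely.  Deterministic given the design's seed.
    """
    if rng is None:
        rng = _rng(design.seed, _K_SETS)
    genes = np.array(design.gene_ids())
    smin, smax = design.set_size_range
    width = len(str(design.n_sets))
    sets: dict[str, GeneSet] = {}
    for i in range(1, design.n_sets + 1):
        size = int(rng.integers(smin, smax + 1))
        members = tuple(rng.choice(genes, size=size, replace=False))
        sid = f"SET{i:0{width}d}"
        sets[sid] = GeneSet(sid, f"synthetic gene set {i}", members)
    return GeneSetCollection(sets, universe=tuple(genes))


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Simulate one full multi-platform study with known ground truth."""
    genes = np.array(design.gene_ids())
    n = design.n_genes

    gene_sets = generate_gene_sets(design)
    planted = tuple(gene_sets.ids()[: design.n_planted_sets])
    # alternate directions so up- and down-regulated planted sets both occur
    directions = {sid: (1 if i % 2 == 0 else -1) for i, sid in enumerate(planted)}
    # gene -> direction of the first planted set containing it
    gene_dir: dict[str, int] = {}
    for sid in planted:
        for g in gene_sets.members_of(sid):
            gene_dir.setdefault(g, directions[sid])

    # DE status ------------------------------------------------------------
    prob = np.full(n, design.de_fraction)
    in_planted = np.array([g in gene_dir for g in genes])
    prob[in_planted] = min(1.0, design.de_fraction * design.planted_de_enrichment)
    de_mask = _rng(design.seed, _K_DE).random(n) < prob

    # effect sizes ---------------------------------------------------------
    rng_eff = _rng(design.seed, _K_EFFECTS)
    delta = np.zeros(n)
    n_de = int(de_mask.sum())
    if n_de:
        a = (0.0 - design.effect_size_log2) / max(design.effect_sd, 1e-12)
        if design.effect_sd > 0:
            mag = stats.truncnorm.rvs(
                a, np.inf, loc=design.effect_size_log2, scale=design.effect_sd,
                size=n_de, random_state=rng_eff,
            )
        else:
            mag = np.full(n_de, design.effect_size_log2)
        signs = np.where(rng_eff.random(n_de) < 0.5, 1.0, -1.0)
        forced = np.array([gene_dir.get(g, 0) for g in genes[de_mask]])
        signs = np.where(forced != 0, forced, signs)
        delta[de_mask] = mag * signs

    # per-gene baseline and noise scale -------------------------------------
    rng_gene = _rng(design.seed, _K_GENE_PARAMS)
    alpha = rng_gene.normal(design.baseline_mean, design.baseline_sd, size=n)
    sigma_g = rng_gene.uniform(*design.gene_sd_range, size=n)

    # per-platform matrices --------------------------------------------------
    studies: list[ExpressionStudy] = []
    n_cov = max(1, int(round(design.platform_coverage * n)))
    for qi, platform in enumerate(design.platforms):
        rng_cov = _rng(design.seed, _K_COVERAGE, qi)
        if design.platform_coverage >= 1.0:
            keep = np.arange(n)
        else:
            keep = np.sort(rng_cov.choice(n, size=n_cov, replace=False))
        rng_noise = _rng(design.seed, _K_NOISE, qi)
        lam = rng_noise.normal(0.0, design.platform_sd, size=len(keep))
        cols: dict[str, np.ndarray] = {}
        design_rows = []
        for si in range(1, design.sites_per_platform + 1):
            nu = rng_noise.normal(0.0, design.site_sd, size=len(keep))
            for cond in ("A", "B"):
                shift = delta[keep] if cond == "A" else 0.0
                for rep in range(1, design.replicates + 1):
                    eps = rng_noise.normal(0.0, sigma_g[keep])
                    sample = f"{platform}_{si}_{cond}{rep}"
                    cols[sample] = alpha[keep] + lam + nu + shift + eps
                    design_rows.append(
                        {"sample_id": sample, "platform": platform,
                         "site": str(si), "condition": cond, "replicate": rep}
                    )
        values = pd.DataFrame(cols, index=genes[keep])
        dsg = pd.DataFrame(design_rows).set_index("sample_id")
        studies.append(ExpressionStudy(values, dsg))

    truth = GroundTruth(
        effects=pd.Series(delta, index=genes, name="delta"),
        planted_sets=planted,
        planted_directions=directions,
    )
    if planted and design.planted_de_enrichment > 1 and 0 < design.de_fraction:
        p_in = min(1.0, design.de_fraction * design.planted_de_enrichment)
        assert p_in > design.de_fraction  # planted sets are enriched by design
    return SyntheticStudy(studies, gene_sets, truth)


def common_genes(studies: Sequence[ExpressionStudy]) -> list[str]:
    """Cross-platform gene intersection, ordered by the first study's order."""
    if not studies:
        raise ParameterError("need at least one study")
    keep = set(studies[0].genes)
    for st in studies[1:]:
        keep &= set(st.genes)
    ordered = [g for g in studies[0].genes if g in keep]
    if not ordered:
        raise AnalysisError("no genes are common to all studies")
    return ordered
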