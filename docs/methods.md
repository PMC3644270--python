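# Methods

`enrichcord` measures how reproducible gene-set (GO-term-style) enrichment
results are when the upstream lists of differentially expressed genes
(DEGs) come from different statistical criteria, different test sites of
one array platform, or different platforms altogether.  Because the
original multi-platform reference data cannot be shipped with a desk-scale
package, every stage runs on a synthetic study with known ground truth;
this note records the models, the defaults and why they were chosen, and
what the synthetic design can and cannot say about real data.

## 1. The synthetic study

### Generative model

For gene *g*, platform *q*, site *s*, condition *c* ∈ {A, B} and replicate
*k*, the observed log2 intensity is

    x = alpha_g + lambda_{g,q} + nu_{g,q,s} + delta_g * 1[c = A] + eps

with `alpha_g ~ N(8, 2^2)` (gene baseline on the log2 scale),
`lambda ~ N(0, platform_sd^2)` (per-platform probe effect),
`nu ~ N(0, site_sd^2)` (per-site offset) and `eps ~ N(0, sigma_g^2)`,
`sigma_g ~ U(gene_sd_range)`.  A gene is differentially expressed with
probability `de_fraction`; DE genes draw `|delta_g|` from
`N(effect_size_log2, effect_sd^2)` truncated at zero and a sign.

Gene sets are random subsets of the transcriptome.  The first
`n_planted_sets` sets are *planted*: their members' DE probability is
multiplied by `planted_de_enrichment` (capped at 1) and their DE members
all take the set's direction (alternating +/− across planted sets; genes
in several planted sets inherit the first set's direction).  Directional
coherence matters: a pre-ranked, signed enrichment walk can only detect a
set whose members cluster at one end of the ranking, and real enriched
categories in a tissue-vs-reference contrast are directionally coherent.
All other DE genes flip a fair coin.

Each platform measures a seeded random `platform_coverage` fraction of the
genes; all statistics are computed on the cross-platform common-gene
intersection, mirroring the common-probe restriction of real
multi-platform comparisons.

### Default desk-scale design

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 2000 | stands in for the ~12k common genes of a real multi-platform study; keeps the full pipeline under two minutes |
| `platforms`, sites, replicates | 3 × 3 × 5 | the reference-sample design the generator emulates |
| `de_fraction` | 0.30 | the emulated contrast (a reference-RNA pair) differs massively; in the real study 30–80% of common genes pass the selection criteria |
| `effect_size_log2`, `effect_sd` | 1.5, 0.7 | a large-contrast regime in which |log2FC| > 1 retains roughly half the DE genes |
| `gene_sd_range` | (0.2, 0.8) | replicate noise of well-behaved arrays, log2 scale |
| `site_sd`, `platform_sd` | 0.2, 0.3 | site/platform offsets visible in baselines |
| `platform_coverage` | 0.85 | three-way intersection ≈ 61% of genes, a visible common-gene restriction |
| `n_sets`, sizes | 150, U(20, 80) | GO-term-like sizes; after the intersection a set keeps ≥ ~12 measured members |
| planted sets | 10, enrichment ×5 | ten ground-truth positives; ×5 caps their DE probability at 1 |

A second named design, `StudyDesign.heteroscedastic_pair()` (2 platforms ×
2 sites, 1500 genes, `gene_sd_range = (0.05, 2.0)`, `site_sd = 0.3`,
120 sets), is the condition under which the three DEG criteria genuinely
disagree: a wide variance range is what separates the variance-sensitive
t-test from the variance-damped fold-change and SAM rules.

### What the generator does not model

Dye bias, spatial artifacts, probe-sequence effects, raw intensities and
normalisation, mean–variance trends, correlated genes, and — importantly —
site×condition interactions: the site offset `nu` is condition-symmetric,
so it shifts baselines but cancels exactly in every A−B contrast.
Passing tests therefore show that the *pipeline machinery* behaves as
specified under a clean additive Gaussian world; they do not certify
concordance levels on any real platform.

## 2. Per-gene statistics and DEG criteria

* **t-test** — pooled-variance two-sided Student t (`df = n_A + n_B − 2`);
  p-values are used directly, with no multiple-testing correction, as in
  the practice the pipeline studies.  Zero pooled variance is handled
  explicitly (t = 0, p = 1 for equal means; p = 0 with an infinite-magnitude
  t otherwise).
* **Fold change** — `log2FC = mean_A − mean_B` on the log2 scale.  The FC
  criterion keeps genes with `t_p < p_cutoff` *and* `|log2FC| > 1`, ranked
  by |log2FC| descending.
* **SAM** — `d = (mean_A − mean_B) / (s + s0)` with *s* the pooled standard
  error.  The fudge factor `s0` is chosen by coefficient-of-variation
  minimisation: candidates are 0 and the 5th–95th percentiles of *s*; for
  each candidate the genes are split into 100 s-quantile windows and the
  candidate minimising the CV of the within-window median absolute
  deviations of *d* wins.  Note the rule's actual geometry: window spreads
  go as `sigma_r,j / (s_j + s0)`, so with one shared variance the CV falls
  monotonically in `s0` (a large fudge factor is selected, and *d* tracks
  the raw mean difference — harmless when variance carries no gene
  information), whereas with noise proportional to `sigma_g` the statistic
  is already pivotal at `s0 = 0` and the rule stays there.
  Significance is a permutation p: for the balanced 5-vs-5 design all
  C(10,5) = 252 label assignments are enumerated exactly (identity counted;
  since the complement assignment duplicates |d|, the smallest attainable p
  is 2/252); larger designs fall back to sampled permutations with +1
  smoothing.  `s0` is held fixed across permutations.
* All orderings break ties lexicographically on the gene id, so DEG lists
  are bit-reproducible.

## 3. Enrichment engines

### Pre-ranked weighted-KS engine (GSEA-style)

The DEG list is ranked by the criterion's native signed metric (FC →
log2FC, SAM → d, t-test → sign(log2FC)·(−log10 p)).  For a set with
`N_hits` in-list members the running sum gains
`|r_j|^w / Σ_hits |r|^w` at hits (default weight `w = 1`) and loses
`1/(N − N_hits)` at misses; ES is the signed extremum.  Because the input
is a pre-ranked *list* rather than an expression matrix, the null permutes
gene-set membership (uniform same-size sets), not sample labels.  NES
divides ES by the magnitude of the same-sign null mean for that set's
size; nulls are shared between sets of equal size.  The FDR q for a
positive set is `[frac of pooled null NES ≥ NES*] / [frac of observed
NES ≥ NES*]` within the non-negative tails, clipped to [0, 1], mirrored
for negatives, and made monotone non-increasing in |NES| within each sign
by a step-up-style pass (a set may inherit a smaller q attained at a
deeper threshold, never the reverse).  Defaults: `n_perm = 1000`,
`min_size = 5` in-list members (a desk-scale collection would starve at
the classic 15), `max_size = 500`, FDR < 0.25 for significance.

### Logistic-regression engine (LRpath-style)

For each set, membership `y` over the full common-gene universe is
regressed on `x = −log(p)`: `logit P(y=1) = b0 + b1*x`, fitted by IRLS
(deviance tolerance 1e-8, ≤100 iterations, via statsmodels GLM/Binomial);
a two-sided Wald test on `b1` gives the set p-value and Benjamini–Hochberg
across sets the q.  Zero p-values are floored at 1e-15; (near-)complete
separation — vanishing deviance or exploding slope/SE — is flagged and the
set excluded from ranking.  A flag restricts the universe to the DEG list
instead; the default stays with the full universe, since a regression
needs non-members across the significance range.

The per-gene significance source follows the criterion under comparison:
t-test → t p-values, SAM → SAM permutation p-values, and fold change → an
empirical rank-based p of |log2FC| (`rank/n`, largest fold change first).
The FC criterion *is* a fold-change ranking, so its significance input is
that ranking; mapping it to t-test p-values instead would make the FC and
t-test runs of this engine literally identical and the comparison between
them vacuous.

## 4. The concordance statistic

Significant terms (q < 0.25, strict) are ranked by q ascending (ties: |NES|
descending for the ranked-list engine, Wald p ascending for the regression
engine, then set id).  Two lists are compared at equal length N (the
shorter list); at depth i,

    POG_i = 100 * |top_i(a) ∩ top_i(b)| / i .

For the ranked-list engine, the positively and negatively enriched lists
are truncated direction-wise to the pairwise minimum and concatenated
(pos block first) before comparison; N is the combined length.  The
terminal value POG_N summarises a pair.  Overlap is undirected by default
(a term counts regardless of its direction label); a direction-aware mode
exists.  An empty significant list on either side yields NA, not 0% —
absence of evidence is not disagreement.  Useful bounds: O_i is
non-decreasing; one step can raise POG by at most 200/(i+1) (each list's
new term can match an earlier term of the other) and lower it by at most
100/(i+1); swapping adjacent terms changes POG_i by at most 100/i.

Comparison families: (i) inter-site within a platform at the same
criterion, (ii) intra-site between criterion pairs (FC–SAM, FC–t,
SAM–t) at matched p cutoff, (iii) inter-platform at the same site and
criterion.

## 5. Numerical and design choices

* One global seed expands into fixed per-component substreams
  (`SeedSequence([seed, key...])`), so changing one design field does not
  reshuffle unrelated draws and every run is bit-reproducible.
* The ES extremum takes the first index of maximal |running sum|; the
  running sum returns to 0 within 1e-9 by construction.
* Gene-set permutation nulls are cached per in-list set size within a run,
  with a per-size seed substream.
* BH is the exact step-up (`q_(i) = min_{j≥i} p_(j)·m/j`, capped at 1).
* Degenerate inputs fail loudly: empty gene-universe intersections,
  all-member or no-member sets, single-class regressions and zero-variance
  genes each have a documented branch or error.

## 6. Problem sizes used by tests and the reproduction script

The test suite and `scripts/acceptance.py` run the full pipeline at the
desk scale described above: the three-platform default design;
null-calibration studies at `de_fraction = 0` (10 seeds for the t-test
size, 5 for each engine); the heteroscedastic two-platform design over 10
seeds with `n_perm = 500` for the ranked-list engine (its null is smooth
at that depth and the study halves in cost); and 2000 random-list trials
for the overlap-percentage null (universe 500, lists of 50, expected
terminal POG `100·N/U = 10%`).  The whole suite completes in roughly two
minutes on one core.

## 7. Known limitations

* Concordance percentages produced here characterise the synthetic
  regime; they are not estimates of any real platform's reproducibility.
* Term identity is exact-match; semantically similar but distinct terms
  count as disagreement (no ontology-graph awareness).
* The regression engine's optional empirical-Bayes weighting and the
  ranked-list engine's phenotype-permutation mode and leading-edge
  extraction are out of scope.
* With fewer than ~100 genes the s0 window rule degenerates to fewer
  windows; below 20 genes it refuses to run.
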