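"""Percentage of overlapping terms between two enrichment runs.

The reproducibility statistic: rank each run's significant terms
(FDR < 0.25) by q, truncate both lists to the shorter length, and report
100 * |top_i(a) & top_i(b)| / i at every depth.  Here the same platform's
two test sites are compared - the intra-platform, inter-site question.
"""

import enrichcord as ec

studies, gene_sets, truth = ec.generate_study(ec.StudyDesign.desk_default(seed=1))
common = ec.common_genes(studies)

term_lists = {}
for site in ("1", "2"):
    stats = ec.compute_gene_statistics(studies[0], site=site,
                                       genes=common, seed=7)
    deg = ec.select_degs(stats, ec.DEGCriterion("SAM", 0.05))
    res = ec.run_gsea(deg, stats, gene_sets, n_perm=1000, seed=3)
    term_lists[site] = ec.rank_significant_terms(res, 0.25)  # (pos, neg)

pos1, neg1 = term_lists["1"]
pos2, neg2 = term_lists["2"]
print(f"site 1: {len(pos1)} pos + {len(neg1)} neg significant terms")
print(f"site 2: {len(pos2)} pos + {len(neg2)} neg significant terms")

a, b, n = ec.combine_pos_neg(pos1, neg1, pos2, neg2)
curve = ec.concordance_curve(a, b)
print(f"\ncombined matched length N = {n}")
print("depth  overlap  POG%")
for i in (1, 2, 5, 10, n):
    if i <= n:
        print(f"{i:5d}  {curve.overlaps[i - 1]:7d}  "
              f"{curve.percentages[i - 1]:6.1f}")
print(f"\nterminal POG (all terms meeting FDR < 0.25): {curve.terminal:.1f}% "
      "- the two sites largely agree on which sets are enriched.")
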