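"""Select differentially expressed genes under the three criteria.

For one site's A-vs-B contrast the per-gene statistics (pooled t, log2 fold
change, SAM d with its permutation p) feed three selection rules:
fold-change ranking behind a loose p filter, SAM, and the plain t-test.
The count table mirrors how such studies report DEG numbers per
platform/site: the t-test always selects the most genes, fold change the
fewest (it adds the |log2FC| > 1 constraint).
"""

import enrichcord as ec

studies, gene_sets, truth = ec.generate_study(ec.StudyDesign.desk_default(seed=1))
common = ec.common_genes(studies)

lists = {}
for study in studies[:2]:                      # two platforms for brevity
    platform = study.platforms[0]
    stats = ec.compute_gene_statistics(study, site="1", genes=common, seed=7)
    print(f"{platform} site 1: s0 = {stats.s0:.3f} "
          f"(SAM fudge factor, chosen by the CV rule)")
    for method in ("FC", "SAM", "TTEST"):
        for cutoff in (0.01, 0.05):
            crit = ec.DEGCriterion(method, cutoff)
            lists[(platform, "1", method, cutoff)] = ec.select_degs(stats, crit)

print()
print(ec.deg_count_table(lists))
print("\nEach cell is the number of genes a criterion selects from the "
      f"{len(common)} common genes; rows are nested within a method.")
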