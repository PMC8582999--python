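"""Simulate partially regulated genes and compare exon-level vs gene-level
detection.

Each DE gene has 2 of its 7 exons shifted two-fold; the summed gene counts
barely move, so conventional gene-level testing misses most of these genes
while exon-level testing with empirical Brown aggregation recovers them.
"""

from featde import SimConfig, simulate, run_de, gene_level_counts, sensitivity_at_fdr

cfg = SimConfig(n_genes=400, exons_per_gene=7, pattern="partial", seed=7)
cm, fm, truth = simulate(cfg)
print(f"simulated {cm.n_features} exons in {cfg.n_genes} genes, "
      f"{int(truth.genes.is_de.sum())} genes DE (2 of 7 exons, 2-fold)")

res_exon = run_de(cm, fm, method="ebm")
gcm, gfm = gene_level_counts(cm, fm)
res_gene = run_de(gcm, gfm, method="fisher", drop_single_feature_genes=False)

is_de = truth.genes["is_de"]
for name, res in (("exon + ebm", res_exon), ("gene-level", res_gene)):
    gt = res["gene_table"]
    sens = sensitivity_at_fdr(gt["p_aggregated"], is_de, fdr=0.05)
    print(f"{name:11s}: {int(gt.deg_flag.sum()):3d} DEGs at FDR<0.05, "
          f"sensitivity {sens:.2f} at matched empirical FDR 0.05")

print()
print("Sensitivity is the fraction of truly DE genes recovered when each")
print("scheme's rejection list is cut at a realized false-discovery")
print("proportion of 5%: the exon-level scheme sees the regulated exons")
print("directly instead of diluting them in the gene total.")
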