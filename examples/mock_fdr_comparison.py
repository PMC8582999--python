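"""Estimate the empirical FDR of two aggregation methods by mock comparisons.

Splitting one biological group against itself 10 times (7 vs 7, sampled
without replacement) yields comparisons with no true signal; every DEG found
there is a false positive.  Dividing the median mock DEG count by the DEG
count of the real between-group comparison estimates the scheme's FDR.
"""

from featde import MockDesign, SimConfig, mock_fdr, simulate
from featde.detest import nb_wald_test, normalize, rle_size_factors
from featde.pipeline import (
    aggregate_to_genes,
    bh_adjust,
    call_degs,
    filter_low_expression,
    remove_single_feature_genes,
)

cm, fm, truth = simulate(SimConfig(n_genes=300, exons_per_gene=7,
                                   pattern="partial", seed=21))


def scheme(mat):
    """One shared NB exon test, aggregated with both methods."""
    s = rle_size_factors(mat.counts)
    filt = remove_single_feature_genes(filter_low_expression(mat, s), fm)
    ft = nb_wald_test(filt, size_factors=s)
    norm = normalize(filt.counts, s)
    out = {}
    for method in ("lancaster", "ebm"):
        gt = aggregate_to_genes(ft, fm, method=method, data=norm)
        gt["fdr"] = bh_adjust(gt["p_aggregated"])
        out[method] = int(call_degs(gt)["deg_flag"].sum())
    return out


result = mock_fdr(cm, MockDesign(subset_size=7, n_repeats=10, seed=3), scheme)
for method in ("lancaster", "ebm"):
    print(f"exon + {method:9s}: median mock FPs = "
          f"{result.fp_counts[method].median():5.1f}, between-group DEGs = "
          f"{result.n_between[method]:3d}, mock FDR = {result.fdr[method]:.3f}")

print()
print("Lancaster ignores the correlation between exons of one gene, so its")
print("false-positive rate inflates in the mock splits; empirical Brown")
print("absorbs the dependence and keeps the mock FDR near zero.")
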