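"""Filtering, harmonization, gene-level aggregation and DEG calling.

The gene-level workflow on a feature count matrix is:

1. RLE size factors and normalization.
2. Expression filter: drop features whose mean normalized count is below 1.
3. Drop genes left with a single exon (their result cannot differ between
   feature levels); when several feature levels are analysed jointly, the
   removal list derived at the exon level is applied to every level and the
   surviving gene sets are intersected (:func:`harmonize_levels`).
4. Per-feature NB Wald test (or injected external statistics).
5. Combine each gene's feature p-values with Fisher, weighted Lancaster
   (weights = mean normalized counts), Brown, or empirical Brown's method.
6. Benjamini–Hochberg correction and DEG calling at FDR < 0.05 (strict).

Features that map to more than one gene (a situation typical of transcript
equivalence classes) are removed before testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import aggregation as agg
from .data import CountMatrix, FeatureMap
from .detest import nb_wald_test, normalize, rle_size_factors

__all__ = [
    "filter_low_expression",
    "remove_single_feature_genes",
    "remove_multigene_features",
    "harmonize_levels",
    "aggregate_to_genes",
    "bh_adjust",
    "call_degs",
    "gene_level_counts",
    "run_de",
]

logger = logging.getLogger(__name__)

METHODS = ("fisher", "lancaster", "brown", "ebm")


def filter_low_expression(cm: CountMatrix, size_factors: pd.Series | None = None,
                          threshold: float = 1.0, how: str = "mean") -> CountMatrix:
    """Drop features with normalized expression below ``threshold``.

    ``how`` selects the per-feature summary of normalized counts compared
    against the threshold: ``mean`` (default), ``min`` or ``max``.  The
    comparison is strict: a feature at exactly the threshold is kept.
    """
    if size_factors is None:
        size_factors = rle_size_factors(cm.counts)
    norm = normalize(cm.counts, size_factors)
    summary = getattr(norm, how)(axis=1)
    keep = summary >= threshold
    n_dropped = int((~keep).sum())
    logger.info("expression filter: %d of %d features removed", n_dropped,
                cm.n_features)
    if not keep.any():
        logger.warning("expression filter removed every feature")
    return cm.subset_features(cm.feature_ids[keep])


def remove_single_feature_genes(cm: CountMatrix, fm: FeatureMap,
                                removal_genes=None) -> CountMatrix:
    """Drop genes with exactly one remaining feature.

    The rule applies after the expression filter: a multi-exon gene reduced to
    one surviving exon is removed.  ``removal_genes`` lets a removal list
    derived at the exon level be applied verbatim to another feature level.
    Returns the filtered matrix; the removed gene list is available via
    :func:`single_feature_genes`.
    """
    if removal_genes is None:
        removal_genes = single_feature_genes(cm, fm)
    genes = fm.genes_of(cm.feature_ids)
    keep = ~genes.isin(set(removal_genes)).to_numpy()
    logger.info("single-feature-gene filter: %d genes (%d features) removed",
                len(set(removal_genes)), int((~keep).sum()))
    return cm.subset_features(cm.feature_ids[keep])


def single_feature_genes(cm: CountMatrix, fm: FeatureMap) -> list:
    """Genes with exactly one feature remaining in ``cm``."""
    genes = fm.genes_of(cm.feature_ids)
    counts = genes.groupby(genes).size()
    return list(counts.index[counts == 1])


def remove_multigene_features(raw_pairs: pd.Series, level: str = "tcc") -> FeatureMap:
    """Build a one-to-one FeatureMap, dropping features tied to several genes.

    ``raw_pairs`` maps each feature ID to either a single gene ID or a
    set/list of gene IDs.  Features associated with more than one distinct
    gene are removed entirely before statistical testing.
    """
    mapping = {}
    n_multi = 0
    for feat, genes in raw_pairs.items():
        if isinstance(genes, str):
            gene_set = {genes}
        else:
            gene_set = set(genes)
        if len(gene_set) == 1:
            mapping[feat] = next(iter(gene_set))
        else:
            n_multi += 1
    logger.info("multi-gene filter: %d of %d features removed", n_multi,
                len(raw_pairs))
    if not mapping:
        logger.warning("multi-gene filter removed every feature")
        return FeatureMap(pd.Series(dtype=object), level=level)
    return FeatureMap(pd.Series(mapping), level=level)


def harmonize_levels(datasets):
    """Restrict every feature level to the common surviving gene set.

    ``datasets`` is a list of (CountMatrix, FeatureMap) pairs, one per feature
    level, each already filtered.  A gene whose features were all removed at
    any level is removed from every level, so the surviving gene set is
    identical across levels (the set intersection).
    """
    if len(datasets) < 2:
        raise ValueError("harmonization needs at least two feature levels")
    gene_sets = []
    for cm, fm in datasets:
        gene_sets.append(set(fm.genes_of(cm.feature_ids).unique()))
    common = set.intersection(*gene_sets)
    if not common:
        raise ValueError("no gene survives at every feature level")
    out = []
    for cm, fm in datasets:
        genes = fm.genes_of(cm.feature_ids)
        keep = genes.isin(common).to_numpy()
        cm2 = cm.subset_features(cm.feature_ids[keep])
        out.append((cm2, fm))
        logger.info("harmonization (%s level): %d genes, %d features kept",
                    fm.level, len(common), cm2.n_features)
    return out


def aggregate_to_genes(ft: pd.DataFrame, fm: FeatureMap, method: str = "ebm",
                       data: pd.DataFrame | None = None,
                       weights: pd.Series | None = None) -> pd.DataFrame:
    """Combine each gene's feature p-values into one gene-level p-value.

    ``ft`` is a feature test table (``p_value``, ``log2fc``,
    ``mean_norm_count``) indexed by feature ID.  ``method`` is one of
    ``fisher``, ``lancaster``, ``brown`` (with the independence correction,
    i.e. identical to Fisher unless a correction is supplied upstream) or
    ``ebm``.  Lancaster weights default to the mean normalized counts; the
    empirical Brown covariance is estimated from ``data`` (normalized feature
    × sample matrix), which is required for ``method='ebm'`` with K >= 2.

    Features with undefined p-values are dropped; genes that lose every
    feature get an undefined (NaN) result row.  Single-feature genes return
    that feature's p-value under every method.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "ebm" and data is None:
        raise ValueError("method 'ebm' requires the normalized data matrix")
    unmapped = ~ft.index.isin(fm.feature_ids)
    if unmapped.any():
        raise ValueError(
            f"{int(unmapped.sum())} features in the test table are not in the map"
        )
    genes = fm.genes_of(ft.index)
    if weights is None:
        weights = ft["mean_norm_count"]

    rows = []
    for gene, idx in ft.groupby(genes.values).groups.items():
        sub = ft.loc[idx]
        defined = sub["p_value"].notna()
        n_dropped = int((~defined).sum())
        sub = sub.loc[defined]
        if sub.empty:
            logger.info("gene %s has no defined feature p-values", gene)
            rows.append((gene, np.nan, 0, ""))
            continue
        p = sub["p_value"].to_numpy()
        if method == "fisher":
            res = agg.fisher_combine(p)
        elif method == "lancaster":
            w = np.maximum(weights.loc[sub.index].to_numpy(dtype=float), 1e-8)
            res = agg.lancaster_combine(p, w)
        elif method == "brown":
            res = agg.brown_combine(
                p, agg.BrownCorrection(c=1.0, f=2.0 * len(p))
            )
        else:  # ebm
            mat = data.loc[sub.index].to_numpy(dtype=float)
            res = agg.empirical_brown_combine(p, mat)
        rows.append((gene, res.p_combined, len(p), ",".join(map(str, sub.index))))
        if n_dropped:
            logger.debug("gene %s: %d undefined features dropped", gene, n_dropped)

    out = pd.DataFrame(rows, columns=["gene_id", "p_aggregated", "n_features",
                                      "feature_ids"]).set_index("gene_id")
    return out.sort_index()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, ties preserved).

    NaN entries are passed through as NaN and excluded from the adjustment.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def call_degs(gene_table: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Flag genes with ``fdr`` strictly below ``threshold`` as DEGs.

    A gene at exactly the threshold is not called.
    """
    out = gene_table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p_aggregated"])
    out["deg_flag"] = (out["fdr"] < threshold).fillna(False)
    out.loc[out["fdr"].isna(), "deg_flag"] = False
    return out


def gene_level_counts(cm: CountMatrix, fm: FeatureMap) -> tuple[CountMatrix, FeatureMap]:
    """Reference gene-level scheme: sum feature counts within each gene.

    Mirrors the conventional workflow in which gene counts are produced by
    summing the counts of the gene's features before testing.
    """
    genes = fm.genes_of(cm.feature_ids)
    summed = cm.counts.groupby(genes.values).sum()
    summed.index.name = "gene_id"
    gm = FeatureMap(pd.Series(summed.index, index=summed.index), level="gene")
    return CountMatrix(summed, cm.groups.copy()), gm


def run_de(cm: CountMatrix, fm: FeatureMap, method: str = "ebm",
           min_norm_expr: float = 1.0, fdr: float = 0.05,
           drop_single_feature_genes: bool = True,
           feature_table: pd.DataFrame | None = None) -> dict:
    """Full feature-level DE workflow on one count matrix.

    Returns a dict with the size factors, the filtered matrix, the feature
    test table and the gene result table (``p_aggregated``, ``fdr``,
    ``n_features``, ``deg_flag``, ``feature_ids``).  Pass ``feature_table`` to
    skip the built-in NB test and aggregate externally computed statistics
    (they are still restricted to the filtered features).
    """
    cm.require_two_groups()
    s = rle_size_factors(cm.counts)
    filtered = filter_low_expression(cm, s, threshold=min_norm_expr)
    if drop_single_feature_genes:
        filtered = remove_single_feature_genes(filtered, fm)
    if filtered.n_features == 0:
        raise ValueError("no features survive filtering")
    logger.info("%d features in %d genes enter testing", filtered.n_features,
                fm.genes_of(filtered.feature_ids).nunique())
    if feature_table is None:
        ft = nb_wald_test(filtered, size_factors=s)
    else:
        ft = feature_table.loc[feature_table.index.isin(filtered.feature_ids)].copy()
    norm = normalize(filtered.counts, s)
    gene_table = aggregate_to_genes(ft, fm, method=method, data=norm)
    gene_table["fdr"] = bh_adjust(gene_table["p_aggregated"])
    gene_table = call_degs(gene_table, threshold=fdr)
    logger.info("%d of %d genes called DE at FDR < %g",
                int(gene_table["deg_flag"].sum()), len(gene_table), fdr)
    return {
        "size_factors": s,
        "filtered": filtered,
        "feature_table": ft,
        "gene_table": gene_table,
    }
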