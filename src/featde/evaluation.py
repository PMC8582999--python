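"""Benchmarking of DE schemes: partial AUC, mock-comparison FDR, gene plots.

Two complementary procedures assess a differential-expression scheme without
complete ground truth:

* :func:`partial_auc` scores gene rankings against a truth set defined by an
  external reference fold-change (e.g. qRT-PCR): genes above a cut-off are
  positives, genes with ``|log2FC| < 0.2`` true negatives, the rest excluded.
  The area under the ROC curve is restricted to specificity above 0.8 (high-
  confidence calls), reported unnormalized (maximum ``1 − spec_min``).
* :func:`mock_fdr` estimates the empirical FDR by splitting one biological
  group against itself: any DEG found between two halves of the same group is
  a false positive, and the median false-positive count over repeated random
  splits is scaled by the DEG count of the real between-group comparison.

:func:`plot_gene` draws the per-feature view of a gene (log2 fold-change bars
with significance stars over mean ± SE normalized counts per group) that makes
partially or discordantly regulated genes interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .data import CountMatrix

__all__ = [
    "build_truth",
    "partial_auc",
    "MockDesign",
    "MockFdrResult",
    "mock_fdr",
    "sensitivity_at_fdr",
    "plot_gene",
]

TRUE_NEGATIVE_BAND = 0.2  # |reference log2FC| below this defines true negatives


def build_truth(ref_log2fc: pd.Series, cutoff: float) -> pd.Series:
    """Label genes positive/negative/excluded from a reference log2FC.

    Positives satisfy ``|ref| >= cutoff``; negatives ``|ref| < 0.2`` (strict);
    genes in between are excluded from evaluation.  ``cutoff`` must be at
    least 0.2 so the classes cannot overlap.
    """
    if cutoff < TRUE_NEGATIVE_BAND:
        raise ValueError(f"cutoff must be >= {TRUE_NEGATIVE_BAND}")
    ref = pd.Series(ref_log2fc, dtype=float)
    a = ref.abs()
    labels = pd.Series("excluded", index=ref.index, dtype=object)
    labels[a >= cutoff] = "positive"
    labels[a < TRUE_NEGATIVE_BAND] = "negative"
    if (labels == "positive").sum() == 0:
        import warnings

        warnings.warn(f"no gene reaches |log2FC| >= {cutoff}", UserWarning,
                      stacklevel=2)
    return labels


def partial_auc(scores: pd.Series, truth: pd.Series, spec_min: float = 0.8,
                normalized: bool = False) -> float:
    """Partial area under the ROC curve for specificity in [spec_min, 1].

    ``scores`` rank the genes with smaller = more likely positive (gene-level
    p-values).  Excluded genes are ignored.  Tied scores form a single
    threshold step and the curve is integrated by the trapezoidal rule, with
    linear interpolation at the specificity boundary; the unnormalized
    maximum is ``1 − spec_min``.
    """
    truth = pd.Series(truth)
    used = truth.isin(["positive", "negative"])
    y = (truth[used] == "positive").to_numpy(dtype=int)
    s = pd.Series(scores).reindex(truth.index[used]).to_numpy(dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores must be defined for every evaluated gene")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("truth set needs at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, -s, drop_intermediate=False)
    fpr_max = 1.0 - spec_min
    # restrict to fpr <= fpr_max, interpolating tpr at the boundary
    inside = fpr <= fpr_max + 1e-12
    fx = fpr[inside]
    ty = tpr[inside]
    if fx[-1] < fpr_max:
        t_b = float(np.interp(fpr_max, fpr, tpr))
        fx = np.append(fx, fpr_max)
        ty = np.append(ty, t_b)
    area = float(np.trapezoid(ty, fx))
    if normalized:
        area /= fpr_max
    return area


def sensitivity_at_fdr(pvalues: pd.Series, is_de: pd.Series,
                       fdr: float = 0.05) -> float:
    """Sensitivity at a matched empirical false-discovery proportion.

    Genes are ranked by p-value; the largest rejection set whose realized
    false-discovery proportion (known truth) is at most ``fdr`` defines the
    operating point, and the fraction of true DE genes recovered there is
    returned.  This compares schemes at equal empirical error rather than at
    equal nominal threshold.
    """
    p = pd.Series(pvalues).dropna()
    truth = pd.Series(is_de).reindex(p.index).astype(bool)
    if truth.sum() == 0:
        raise ValueError("no true DE genes in the truth set")
    order = np.argsort(p.to_numpy(), kind="stable")
    t = truth.to_numpy()[order]
    ranks = np.arange(1, t.size + 1)
    fdp = np.cumsum(~t) / ranks
    ok = np.where(fdp <= fdr)[0]
    if ok.size == 0:
        return 0.0
    k = ok[-1] + 1
    return float(t[:k].sum() / truth.sum())


@dataclass(frozen=True)
class MockDesign:
    """Within-group split design for empirical FDR estimation.

    Each repeat draws ``2 * subset_size`` samples without replacement from the
    chosen group and halves them into two pseudo-groups; when the group has
    exactly ``2 * subset_size`` samples the random split itself is what varies
    across repeats.
    """

    subset_size: int = 7
    n_repeats: int = 10
    seed: int = 0


@dataclass
class MockFdrResult:
    fdr: dict
    fp_counts: pd.DataFrame
    n_between: dict


def mock_fdr(cm: CountMatrix, design: MockDesign, scheme,
             group=None, between_degs=None) -> MockFdrResult:
    """Empirical FDR of a DE scheme from within-group mock comparisons.

    ``scheme`` is a callable ``CountMatrix -> int`` (DEG count) or
    ``CountMatrix -> dict[str, int]`` for several aggregation methods sharing
    one feature-level test.  It is run on ``n_repeats`` random within-group
    splits of ``group`` (default: first group level); every DEG found there is
    a false positive.  The estimate is ``median FP count / DEG count of the
    real between-group comparison``; the denominator is computed by running
    ``scheme`` on the full matrix unless ``between_degs`` is supplied.  A zero
    denominator yields NaN.
    """
    levels = cm.group_levels
    if group is None:
        group = levels[0]
    members = list(cm.sample_ids[(cm.groups == group).to_numpy()])
    need = 2 * design.subset_size
    if len(members) < need:
        raise ValueError(
            f"group {group!r} has {len(members)} samples; {need} required"
        )
    rng = np.random.default_rng(design.seed)

    def as_dict(result):
        return dict(result) if isinstance(result, dict) else {"scheme": int(result)}

    records = []
    for rep in range(design.n_repeats):
        chosen = rng.choice(members, size=need, replace=False)
        labels = ["mockA"] * design.subset_size + ["mockB"] * design.subset_size
        mock = cm.subset_samples(list(chosen), groups=labels)
        records.append(as_dict(scheme(mock)))
    fp = pd.DataFrame.from_records(records)
    fp.index.name = "repeat"

    if between_degs is None:
        between = as_dict(scheme(cm))
    else:
        between = as_dict(between_degs)

    est = {}
    for key in fp.columns:
        denom = between.get(key, 0)
        est[key] = float(fp[key].median()) / denom if denom > 0 else float("nan")
    return MockFdrResult(fdr=est, fp_counts=fp, n_between=between)


_STAR_BOUNDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    for bound, mark in _STAR_BOUNDS:
        if p < bound:
            return mark
    return ""


def plot_gene(gene_id: str, ft: pd.DataFrame, norm_counts: pd.DataFrame,
              groups: pd.Series, fm=None, fdr: float | None = None,
              path=None):
    """Two-panel per-feature view of one gene.

    Upper panel: log2 fold-change of each feature with significance stars
    (``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001, strict bounds).  Lower
    panel: mean ± standard error of the normalized counts per group.  The
    gene ID (and FDR, if given) go in the title.  Returns the figure; saves
    to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if fm is not None:
        feats = [f for f in ft.index if fm.genes_of([f]).iloc[0] == gene_id]
    elif "gene_id" in ft.columns:
        feats = list(ft.index[ft["gene_id"] == gene_id])
    else:
        feats = [f for f in ft.index if str(f).startswith(str(gene_id))]
    if not feats:
        raise ValueError(f"unknown gene {gene_id!r}: no features found")
    sub = ft.loc[feats]
    groups = pd.Series(groups).reindex(norm_counts.columns)
    levels = list(dict.fromkeys(groups))

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(max(4, 0.6 * len(feats)), 6),
                                   sharex=True)
    xs = np.arange(len(feats))
    lfc = sub["log2fc"].to_numpy(dtype=float)
    ax1.bar(xs, lfc, color="steelblue")
    ax1.axhline(0, color="black", lw=0.8)
    span = max(1.0, np.nanmax(np.abs(lfc)))
    for i, f in enumerate(feats):
        mark = _stars(float(sub.loc[f, "p_value"]))
        if mark:
            offset = 0.05 * span * (1 if lfc[i] >= 0 else -1)
            ax1.text(i, lfc[i] + offset, mark, ha="center",
                     va="bottom" if lfc[i] >= 0 else "top")
    ax1.set_ylabel("log2 fold-change")
    title = str(gene_id) if fdr is None else f"{gene_id} (FDR = {fdr:.3g})"
    ax1.set_title(title)

    width = 0.35
    for gi, level in enumerate(levels):
        cols = norm_counts.columns[(groups == level).to_numpy()]
        vals = norm_counts.loc[feats, cols]
        mean = vals.mean(axis=1).to_numpy()
        se = vals.std(axis=1, ddof=1).to_numpy() / np.sqrt(len(cols))
        ax2.bar(xs + (gi - 0.5) * width, mean, width=width, yerr=se,
                capsize=2, label=str(level))
    ax2.set_ylabel("normalized count (mean ± SE)")
    ax2.set_xticks(xs)
    ax2.set_xticklabels([str(f) for f in feats], rotation=90, fontsize=7)
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
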