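"""Tests of truth-set construction, partial AUC, mock FDR and gene plots."""

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

from featde.data import CountMatrix
from featde.evaluation import (
    MockDesign,
    build_truth,
    mock_fdr,
    partial_auc,
    plot_gene,
    sensitivity_at_fdr,
)


def _brute_force_pauc(scores, labels, spec_min=0.8):
    """Oracle: exhaustive threshold enumeration + trapezoid in FPR.

    Thresholds sweep every distinct score (ties form one step); the area is
    accumulated over FPR in [0, 1 - spec_min] with boundary interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    pts = [(0.0, 0.0)]
    for t in sorted(np.unique(scores)):
        called = scores <= t  # small score = called positive
        pts.append(((called & (labels == 0)).sum() / n_neg,
                    (called & (labels == 1)).sum() / n_pos))
    pts = sorted(set(pts))
    fmax = 1.0 - spec_min
    area = 0.0
    for (f1, t1), (f2, t2) in zip(pts, pts[1:]):
        lo, hi = f1, min(f2, fmax)
        if hi <= lo:
            continue
        # linear interpolation of tpr on [lo, hi]
        def tp(f):
            return t1 + (t2 - t1) * (f - f1) / (f2 - f1) if f2 > f1 else t2
        area += 0.5 * (tp(lo) + tp(hi)) * (hi - lo)
    return area


class TestBuildTruth:
    def test_three_way_labels(self):
        ref = pd.Series({"gA": 3.0, "gB": 0.1, "gC": 0.4})
        labels = build_truth(ref, cutoff=0.5)
        assert labels.tolist() == ["positive", "negative", "excluded"]

    def test_boundary_exactly_band_is_excluded(self):
        labels = build_truth(pd.Series({"g": 0.2}), cutoff=0.5)
        assert labels["g"] == "excluded"

    def test_unreachable_cutoff_warns(self):
        with pytest.warns(UserWarning, match="no gene"):
            build_truth(pd.Series({"g": 1.0, "h": 0.05}), cutoff=5.0)

    def test_cutoff_below_band_rejected(self):
        with pytest.raises(ValueError):
            build_truth(pd.Series({"g": 1.0}), cutoff=0.1)


class TestPartialAuc:
    def _truth(self, labels, index=None):
        idx = index or [f"g{i}" for i in range(len(labels))]
        return pd.Series(labels, index=idx)

    def test_perfect_separation_reaches_corner_area(self):
        truth = self._truth(["positive"] * 5 + ["negative"] * 5)
        scores = pd.Series(np.r_[np.full(5, 1e-4), np.full(5, 0.9)],
                           index=truth.index)
        assert partial_auc(scores, truth) == pytest.approx(0.2)

    def test_chance_level_scores(self, rng):
        n = 4000
        truth = self._truth(["positive"] * n + ["negative"] * n)
        scores = pd.Series(rng.uniform(size=2 * n), index=truth.index)
        assert partial_auc(scores, truth) == pytest.approx(0.02, abs=0.005)

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 1)  # force some ties
            truth = self._truth(
                ["positive" if y else "negative" for y in labels]
            )
            s = pd.Series(scores, index=truth.index)
            assert partial_auc(s, truth) == pytest.approx(
                _brute_force_pauc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_score_transform(self, rng):
        n = 60
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=n)
        truth = self._truth(["positive" if y else "negative" for y in labels])
        a = partial_auc(pd.Series(scores, index=truth.index), truth)
        b = partial_auc(pd.Series(np.exp(5 * scores), index=truth.index), truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_normalized_option_scales_by_window(self):
        truth = self._truth(["positive"] * 3 + ["negative"] * 3)
        scores = pd.Series([0.01, 0.01, 0.01, 0.9, 0.9, 0.9], index=truth.index)
        assert partial_auc(scores, truth, normalized=True) == pytest.approx(1.0)

    def test_degenerate_truth_raises(self):
        truth = self._truth(["positive", "excluded"])
        with pytest.raises(ValueError):
            partial_auc(pd.Series([0.1, 0.2], index=truth.index), truth)


class TestSensitivityAtFdr:
    def test_clean_separation_recovers_all(self):
        p = pd.Series({"a": 1e-6, "b": 1e-5, "c": 0.6, "d": 0.9})
        truth = pd.Series({"a": True, "b": True, "c": False, "d": False})
        assert sensitivity_at_fdr(p, truth) == 1.0

    def test_early_false_positive_limits_cut(self):
        p = pd.Series({"fp": 1e-8, "a": 1e-6, "b": 1e-5, "c": 0.6})
        truth = pd.Series({"fp": False, "a": True, "b": True, "c": False})
        # any nonempty rejection set has FDP >= 1/3 > 0.05
        assert sensitivity_at_fdr(p, truth, fdr=0.05) == 0.0
        assert sensitivity_at_fdr(p, truth, fdr=1 / 3) == 1.0


def _mock_cm(n_per_group=14, n_features=30, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.poisson(40, size=(n_features, 2 * n_per_group))
    counts = pd.DataFrame(y, index=[f"f{i}" for i in range(n_features)],
                          columns=[f"s{j}" for j in range(2 * n_per_group)])
    groups = pd.Series(["normal"] * n_per_group + ["tumour"] * n_per_group,
                       index=counts.columns)
    return CountMatrix(counts, groups)


class TestMockFdr:
    def test_scheme_without_mock_degs_gives_zero(self):
        cm = _mock_cm()
        res = mock_fdr(cm, MockDesign(seed=1), lambda m: 0,
                       between_degs={"scheme": 50})
        assert res.fdr["scheme"] == 0.0

    def test_constant_scheme_gives_fdr_one(self):
        # mocks find as many "DEGs" as the real comparison: FDR estimate 1
        cm = _mock_cm()
        res = mock_fdr(cm, MockDesign(seed=1), lambda m: 7)
        assert res.fdr["scheme"] == 1.0

    def test_zero_between_degs_reported_as_nan(self):
        cm = _mock_cm()
        res = mock_fdr(cm, MockDesign(seed=1), lambda m: 0)
        assert np.isnan(res.fdr["scheme"])

    def test_reproducible_given_seed(self):
        cm = _mock_cm()
        calls = []

        def scheme(m):
            calls.append(tuple(m.sample_ids))
            return int(m.counts.iloc[0].sum()) % 5

        r1 = mock_fdr(cm, MockDesign(seed=42), scheme, between_degs=3)
        first = list(calls)
        calls.clear()
        r2 = mock_fdr(cm, MockDesign(seed=42), scheme, between_degs=3)
        assert first == calls
        assert r1.fdr == r2.fdr
        assert r1.fp_counts.equals(r2.fp_counts)

    def test_mock_splits_stay_within_group(self):
        cm = _mock_cm()
        seen = []

        def scheme(m):
            seen.extend(m.sample_ids)
            assert set(m.groups) == {"mockA", "mockB"}
            return 0

        mock_fdr(cm, MockDesign(n_repeats=3, seed=0), scheme,
                 between_degs={"scheme": 1}, group="normal")
        normal = set(cm.sample_ids[(cm.groups == "normal").to_numpy()])
        assert set(seen) <= normal

    def test_too_small_group_raises(self):
        cm = _mock_cm(n_per_group=10)
        with pytest.raises(ValueError, match="required"):
            mock_fdr(cm, MockDesign(subset_size=7), lambda m: 0)

    def test_dict_scheme_returns_per_method_estimates(self):
        cm = _mock_cm()
        res = mock_fdr(cm, MockDesign(seed=3), lambda m: {"x": 1, "y": 0},
                       between_degs={"x": 10, "y": 10})
        assert res.fdr == {"x": 0.1, "y": 0.0}


class TestPlotGene:
    def _ft(self, pvals):
        ids = [f"gX:E{i + 1}" for i in range(len(pvals))]
        return pd.DataFrame({"p_value": pvals,
                             "log2fc": np.linspace(-1, 2, len(pvals)),
                             "mean_norm_count": 20.0,
                             "gene_id": "gX"}, index=ids)

    def _norm(self, n_feat, rng):
        cols = [f"s{j}" for j in range(8)]
        return (pd.DataFrame(rng.uniform(10, 50, size=(n_feat, 8)),
                             index=[f"gX:E{i + 1}" for i in range(n_feat)],
                             columns=cols),
                pd.Series(["a"] * 4 + ["b"] * 4, index=cols))

    def test_star_count_matches_significant_features(self, rng):
        ft = self._ft([0.001, 0.02, 0.04, 0.2, 0.6, 0.0005, 0.03])
        norm, groups = self._norm(7, rng)
        fig = plot_gene("gX", ft, norm, groups)
        stars = [t for t in fig.axes[0].texts if "*" in t.get_text()]
        assert len(stars) == 5
        plt.close(fig)

    def test_boundary_p_gets_no_star(self, rng):
        ft = self._ft([0.05])
        norm, groups = self._norm(1, rng)
        fig = plot_gene("gX", ft, norm, groups)
        assert [t for t in fig.axes[0].texts if "*" in t.get_text()] == []
        plt.close(fig)

    def test_single_feature_gene_plots(self, rng, tmp_path):
        ft = self._ft([0.01])
        norm, groups = self._norm(1, rng)
        out = tmp_path / "gX.png"
        fig = plot_gene("gX", ft, norm, groups, fdr=0.004, path=out)
        assert out.exists()
        assert "gX" in fig.axes[0].get_title()
        plt.close(fig)

    def test_unknown_gene_raises(self, rng):
        ft = self._ft([0.01])
        norm, groups = self._norm(1, rng)
        with pytest.raises(ValueError, match="unknown gene"):
            plot_gene("gZ", ft, norm, groups)
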