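"""Group statistics, k-means / network classification, GA feature search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leafletkit.stats_classify import (
    ann_classify,
    compare_groups,
    ga_select_features,
    kmeans_classify,
    morphospace_ellipsoids,
)


def gaussian_table(centers, n_per=30, sd=1.0, n_noise=0, seed=0):
    """Labeled table of isotropic Gaussian groups (+ optional noise columns)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, center in enumerate(centers):
        center = np.atleast_1d(np.asarray(center, dtype=float))
        for _ in range(n_per):
            vals = center + rng.normal(0, sd, len(center))
            row = {"group": f"G{g}"}
            row.update({f"f{j:02d}": v for j, v in enumerate(vals)})
            row.update({
                f"n{j:02d}": rng.normal() for j in range(n_noise)
            })
            rows.append(row)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_strong_separation_detected(self):
        tab = gaussian_table([[0.0], [5.0]], n_per=30, seed=1)
        cmp = compare_groups(tab, "f00")
        assert cmp.anova_p < 1e-6
        assert cmp.kruskal_p < 1e-6
        assert all(cmp.significant_pairs.values())

    def test_null_rarely_significant(self):
        # empirical type-I behavior at alpha = 0.05 over seeded replicates
        hits = 0
        for seed in range(40):
            tab = gaussian_table([[10.0], [10.0]], n_per=30, seed=seed)
            cmp = compare_groups(tab, "f00")
            hits += cmp.anova_p < 0.05
        assert hits / 40 <= 0.15

    def test_summary_fields(self):
        tab = gaussian_table([[0.0], [5.0]], n_per=12, seed=2)
        cmp = compare_groups(tab, "f00")
        for g in cmp.groups.values():
            assert g["n"] == 12
            assert g["sem"] == pytest.approx(
                g["dispersion"] * abs(g["mean"]) / np.sqrt(12), rel=1e-6
            )

    def test_single_group_rejected(self):
        tab = gaussian_table([[0.0]])
        with pytest.raises(ValueError):
            compare_groups(tab, "f00")


class TestKMeans:
    def test_separable_groups_perfect(self):
        centers = np.eye(3)[:3] * 10.0
        centers = np.vstack([centers, [10.0, 10.0, 10.0]])
        tab = gaussian_table(centers, n_per=25, seed=3)
        res = kmeans_classify(tab, ("f00", "f01", "f02"), seed=0)
        assert res.accuracy == 1.0
        assert res.confusion_matrix.sum(axis=1).tolist() == [25] * 4

    def test_degenerate_identical_samples(self):
        tab = gaussian_table([[1.0, 1.0, 1.0]] * 3, n_per=10, sd=0.0, seed=0)
        res = kmeans_classify(tab, ("f00", "f01", "f02"), seed=0)
        # oracle: best constant assignment = max group size / total
        assert res.accuracy <= 10 / 30 + 0.15

    def test_determinism(self):
        tab = gaussian_table([[0, 0], [3, 3], [6, 0], [0, 6]], n_per=20, seed=4)
        r1 = kmeans_classify(tab, ("f00", "f01"), seed=9)
        r2 = kmeans_classify(tab, ("f00", "f01"), seed=9)
        assert (r1.confusion_matrix == r2.confusion_matrix).all()

    def test_rescaling_invariance(self):
        tab = gaussian_table([[0, 0], [4, 4], [8, 0], [0, 8]], n_per=20, seed=5)
        r1 = kmeans_classify(tab, ("f00", "f01"), seed=2)
        tab2 = tab.copy()
        tab2["f00"] *= 1e4  # px^2-scale column next to a ratio-scale column
        r2 = kmeans_classify(tab2, ("f00", "f01"), seed=2)
        assert r1.accuracy == r2.accuracy

    def test_k_exceeding_samples_rejected(self):
        tab = gaussian_table([[0.0], [5.0]], n_per=3)
        with pytest.raises(ValueError):
            kmeans_classify(tab, ("f00",), k=10)


class TestANN:
    def test_linearly_separable(self):
        tab = gaussian_table([[0.0, 0.0], [8.0, 8.0]], n_per=40, seed=6)
        res = ann_classify(tab, ("f00", "f01"), n_repeats=10, seed=0)
        assert res.accuracy >= 0.99

    def test_chance_level_on_permuted_labels(self):
        rng = np.random.default_rng(7)
        tab = gaussian_table([[0.0, 0.0]] * 6, n_per=30, seed=7)
        tab["group"] = rng.permutation(tab["group"].to_numpy())
        res = ann_classify(tab, ("f00", "f01"), n_repeats=15, seed=1)
        assert abs(res.accuracy - 1 / 6) <= 0.08

    def test_determinism(self):
        tab = gaussian_table([[0, 0], [4, 4], [0, 6], [6, 0]], n_per=12, seed=8)
        feats = ("f00", "f01")
        assert ann_classify(tab, feats, n_repeats=5, seed=3).accuracy == \
            ann_classify(tab, feats, n_repeats=5, seed=3).accuracy

    def test_small_group_error_names_group(self):
        tab = gaussian_table([[0.0], [5.0]], n_per=10, seed=9)
        tab = tab.drop(tab[tab.group == "G1"].index[3:])  # G1 left with 3
        with pytest.raises(ValueError, match="G1"):
            ann_classify(tab, ("f00",))

    def test_confusion_row_sums(self):
        tab = gaussian_table([[0, 0], [6, 6], [0, 6]], n_per=16, seed=10)
        res = ann_classify(tab, ("f00", "f01"), n_repeats=8, seed=2)
        per_repeat_test = int(round(48 * 0.25))
        assert res.confusion_matrix.sum() == per_repeat_test * 8


class TestGeneticAlgorithm:
    def test_matches_exhaustive_on_six_features(self):
        tab = gaussian_table(
            [[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6]],
            n_per=15, n_noise=3, seed=11,
        )
        hits = ga_select_features(tab, classifier="kmeans", subset_size=3,
                                  min_accuracy=0.0, seed=5,
                                  population_size=20, generations=20)
        ga_best = hits[0][1]
        feats = [c for c in tab.columns if c != "group"]
        exhaustive = max(
            kmeans_classify(tab, s, seed=5).accuracy
            for s in itertools.combinations(feats, 3)
        )
        assert ga_best == pytest.approx(exhaustive)

    def test_unreachable_accuracy_empty(self):
        tab = gaussian_table([[0, 0, 0], [6, 6, 6]], n_per=10, n_noise=1,
                             seed=12)
        hits = ga_select_features(tab, classifier="kmeans", subset_size=3,
                                  min_accuracy=1.01, seed=0,
                                  population_size=10, generations=5)
        assert hits == []


class TestMorphospace:
    def test_identical_points_zero_covariance(self):
        tab = gaussian_table([[2.0, 3.0, 4.0]], n_per=6, sd=0.0)
        ell = morphospace_ellipsoids(tab, ("f00", "f01", "f02"))
        assert np.allclose(ell[0].covariance, 0.0)
        assert np.allclose(ell[0].center, [2, 3, 4])

    def test_isotropic_gaussian_semi_axes(self):
        tab = gaussian_table([[0.0, 0.0, 0.0]], n_per=500, sd=1.0, seed=13)
        ell = morphospace_ellipsoids(tab, ("f00", "f01", "f02"))[0]
        expected = np.sqrt(stats.chi2.ppf(0.95, 3))  # 2.7955...
        assert np.allclose(ell.semi_axes(), expected, rtol=0.05)

    def test_distant_groups_disjoint(self):
        tab = gaussian_table([[0.0, 0, 0], [10.0, 10, 10]], n_per=60, seed=14)
        e1, e2 = morphospace_ellipsoids(tab, ("f00", "f01", "f02"))
        gap = np.linalg.norm(e1.center - e2.center)
        assert gap > e1.semi_axes().max() + e2.semi_axes().max()

    def test_small_group_skipped_with_warning(self):
        tab = gaussian_table([[0.0, 0, 0]], n_per=3)
        with pytest.warns(UserWarning, match="skipped"):
            out = morphospace_ellipsoids(tab, ("f00", "f01", "f02"))
        assert out == []
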