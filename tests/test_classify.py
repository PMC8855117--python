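import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster

from astromorph import morpho_classify as mc

import _oracles as orc


class TestMMI:
    def test_two_point_symmetric(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=10_000).astype(float)
        assert mc.multimodality_index(x).mmi == pytest.approx(1.0, abs=0.02)

    def test_normal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=10_000)
        assert mc.multimodality_index(x).mmi == pytest.approx(1 / 3, abs=0.02)

    def test_uniform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=10_000)
        assert mc.multimodality_index(x).mmi == pytest.approx(5 / 9, abs=0.02)

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError):
            mc.multimodality_index(np.ones(10))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(a=st.floats(0.1, 100.0), b=st.floats(-50.0, 50.0),
           seed=st.integers(0, 10_000))
    def test_location_scale_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=64)
        m0 = mc.multimodality_index(x).mmi
        m1 = mc.multimodality_index(a * x + b).mmi
        assert m1 == pytest.approx(m0, rel=1e-9)


class TestSelectFeatures:
    def _frame(self, rng):
        n = 400
        bimodal = np.concatenate([rng.normal(0, 1, n // 2),
                                  rng.normal(8, 1, n // 2)])
        return pd.DataFrame({"bimodal": bimodal,
                             "gaussian": rng.normal(size=n)})

    def test_bimodal_kept_unimodal_dropped(self):
        df = self._frame(np.random.default_rng(0))
        assert mc.select_features(df) == ["bimodal"]

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(1)
        n = 400
        weak = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(4, 1, n // 2)])
        strong = np.concatenate([rng.normal(0, 1, n // 2), rng.normal(20, 1, n // 2)])
        df = pd.DataFrame({"weak": weak, "strong": strong})
        mmi_weak = mc.multimodality_index(weak).mmi
        # exactly-at-threshold feature is dropped: the inequality is strict
        assert mc.select_features(df, threshold=mmi_weak) == ["strong"]

    def test_empty_selection_is_pipeline_error(self):
        df = self._frame(np.random.default_rng(2))[["gaussian"]]
        with pytest.raises(ValueError, match="threshold"):
            mc.select_features(df, threshold=0.55)


class TestShrinkLogTransform:
    def test_decimal_log_and_unit_variance(self):
        df = pd.DataFrame({"f": [1.0, 10.0, 100.0]})
        out = mc.shrink_log_transform(df)
        assert out["f"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(np.diff(out["f"]), [1.0, 1.0])

    def test_monotone_order_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"f": rng.lognormal(size=50)})
        out = mc.shrink_log_transform(df)
        assert (np.argsort(df["f"].to_numpy())
                == np.argsort(out["f"].to_numpy())).all()

    def test_zero_triggers_log1p_fallback(self):
        df = pd.DataFrame({"f": [0.0, 9.0, 99.0]})
        out = mc.shrink_log_transform(df)
        assert out.attrs["log1p_features"] == ["f"]
        sd = np.std(np.log10(df["f"] + 1), ddof=1)
        np.testing.assert_allclose(out["f"], np.log10(df["f"] + 1) / sd)


class TestWardCluster:
    def test_three_blobs(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [5, 0], [0, 5]], float)
        X = np.vstack([rng.normal(c, 0.1, size=(20, 2)) for c in centers])
        df = pd.DataFrame(X, columns=["a", "b"],
                          index=[f"c{i}" for i in range(60)])
        res = mc.ward_cluster(df)
        assert res.k == 3
        from sklearn.metrics import adjusted_rand_score
        truth = np.repeat([0, 1, 2], 20)
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_duplicated_points_two_groups(self):
        X = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([4.0, 4.0], (5, 1))])
        df = pd.DataFrame(X, columns=["a", "b"])
        res = mc.ward_cluster(df)
        assert res.k == 2
        assert np.allclose(res.merge_heights[:8], 0.0)

    def test_matches_naive_ward_oracle(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.uniform(size=(8, 3))
            df = pd.DataFrame(X, columns=list("abc"))
            res = mc.ward_cluster(df, k_range=(2, 4))
            heights, partitions = orc.naive_ward(X)
            np.testing.assert_allclose(res.merge_heights, heights, rtol=1e-9)
            for k in range(2, 8):
                got = fcluster(res.linkage, t=k, criterion="maxclust")
                want = np.empty(8, int)
                for lbl, members in enumerate(partitions[k]):
                    for m in members:
                        want[m] = lbl
                assert adjusted_rand_score(got, want) == 1.0

    def test_too_few_cells(self):
        df = pd.DataFrame(np.random.default_rng(0).uniform(size=(6, 2)))
        with pytest.raises(ValueError):
            mc.ward_cluster(df)


class TestDiscriminant:
    def test_separation_along_one_feature(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame({
            "signal": np.r_[rng.normal(0, 1, n), rng.normal(8, 1, n)],
            "noise": rng.normal(size=2 * n),
        })
        labels = np.repeat([1, 2], n)
        out = mc.discriminant_validation(df, labels)
        assert out.pct_variance[0] == pytest.approx(100.0, abs=1e-6)
        assert out.accuracy_pct >= 99.0
        assert out.features[0] == "signal"

    def test_random_labels_wilks_near_one(self):
        rng = np.random.default_rng(1)
        lams = []
        for _ in range(200):
            X = rng.normal(size=(40, 2))
            y = rng.integers(1, 3, size=40)
            if len(np.unique(y)) < 2:
                continue
            lams.append(orc_wilks := _full_wilks(X, y))
        assert np.mean(lams) == pytest.approx(1.0, abs=0.1)

    def test_univariate_two_group_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30) + np.repeat([0.0, 1.0], 15)
        y = np.repeat([1, 2], 15)
        df = pd.DataFrame({"x": x})
        out = mc.discriminant_validation(df, y, alpha=1.1)  # force entry
        ssw = sum(((x[y == g] - x[y == g].mean()) ** 2).sum() for g in (1, 2))
        sst = ((x - x.mean()) ** 2).sum()
        assert out.wilks_lambda[0] == pytest.approx(ssw / sst, rel=1e-9)

    def test_wilks_eigenvalue_identity(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(90, 4))
        X[:30, 0] += 4
        X[30:60, 1] += 4
        y = np.repeat([1, 2, 3], 30)
        out = mc.discriminant_validation(pd.DataFrame(X, columns=list("abcd")), y)
        for j in range(len(out.wilks_lambda)):
            assert out.wilks_lambda[j] == pytest.approx(
                np.prod(1 / (1 + out.eigenvalues[j:])), rel=1e-12)


def _full_wilks(X, y):
    """Wilks lambda with all features entered (det ratio)."""
    T = np.cov(X.T, ddof=1) * (len(X) - 1)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        W += np.cov(Xg.T, ddof=1) * (len(Xg) - 1)
    return np.linalg.det(W) / np.linalg.det(T)


class TestRepresentativeCell:
    def test_singleton_cluster(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        out = mc.representative_cell(df, [1, 2, 2])
        assert out[1] == "a"

    def test_one_dimensional_example(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        assert mc.representative_cell(df, [1, 1, 1])[1] == "b"

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(20, 3))
        ids = [f"c{i:02d}" for i in range(20)]
        df = pd.DataFrame(X, index=ids)
        got = mc.representative_cell(df, np.ones(20, int))[1]
        sums = [(sum(np.linalg.norm(X[i] - X[j]) for j in range(20)), ids[i])
                for i in range(20)]
        want = min(sums)[1]
        assert got == want


class TestKernelDensityPeaks:
    def test_single_gaussian_one_peak(self):
        rng = np.random.default_rng(0)
        n, _ = mc.kernel_density_peaks(rng.normal(size=500))
        assert n == 1

    def test_three_components(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(c, 1.0, 200) for c in (0, 8, 16)])
        n, locs = mc.kernel_density_peaks(x)
        assert n == 3
        assert np.allclose(sorted(locs), [0, 8, 16], atol=1.0)

    def test_four_components(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(c, 1.0, 150) for c in (0, 8, 16, 24)])
        assert mc.kernel_density_peaks(x)[0] == 4

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError):
            mc.kernel_density_peaks(np.ones(20))
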