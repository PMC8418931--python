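"""SMOTE resampling: ratios, neighbours, synthesis geometry, balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pharmrisk import SmoteConfig, balance_classes, imbalance_ratio, synthesize
from pharmrisk.errors import DegenerateClassError, NeighborError
from pharmrisk.smote import nearest_minority_neighbors


def dataset(class_counts: dict[int, int], n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, n in class_counts.items():
        rows.append(rng.random((n, n_features)) + cls)  # clustered per class
        labels += [cls] * n
    X = np.vstack(rows)
    index = [f"d{i}" for i in range(len(X))]
    return (
        pd.DataFrame(X, index=index, columns=[f"f{j}" for j in range(n_features)]),
        pd.Series(labels, index=index),
    )


class TestImbalanceRatio:
    @pytest.mark.parametrize(
        "major,minor,expected_k", [(887, 47, 18), (887, 113, 7), (10, 10, 1)]
    )
    def test_floored_oversampling_rate(self, major, minor, expected_k):
        ir, k = imbalance_ratio(major, minor)
        assert ir == pytest.approx(major / minor)
        assert k == expected_k

    def test_empty_minority_rejected(self):
        with pytest.raises(DegenerateClassError):
            imbalance_ratio(10, 0)


class TestNearestNeighbors:
    def test_forced_ordering_on_a_line(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0]])
        assert set(nearest_minority_neighbors(0, pts, 2)) == {1, 2}

    def test_self_distance_zero_and_excluded(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        neigh = nearest_minority_neighbors(0, pts, 2)
        assert 0 not in neigh
        assert neigh[0] == 1  # the coincident point is nearest

    def test_matches_exhaustive_distance_sort(self):
        rng = np.random.default_rng(8)
        pts = rng.random((20, 5))
        for i in range(20):
            got = nearest_minority_neighbors(i, pts, 5)
            d = np.sqrt(((pts - pts[i]) ** 2).sum(axis=1))
            order = sorted(range(20), key=lambda j: (d[j], j))
            expected = [j for j in order if j != i][:5]
            assert list(got) == expected

    def test_too_small_class_rejected(self):
        with pytest.raises(NeighborError):
            nearest_minority_neighbors(0, np.zeros((3, 2)), 3)


class TestSynthesize:
    def test_u_zero_returns_base(self):
        x, nb = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert np.allclose(synthesize(x, nb, 0.0), x)

    def test_interpolate_vs_extrapolate_conventions(self):
        x, nb = np.zeros(2), np.ones(2)
        assert np.allclose(synthesize(x, nb, 0.5, "interpolate"), [0.5, 0.5])
        assert np.allclose(synthesize(x, nb, 0.5, "extrapolate"), [-0.5, -0.5])

    @given(u=st.floats(0.01, 0.99), t=st.floats(-1, 1))
    @settings(derandomize=True, max_examples=40)
    def test_collinearity(self, u, t):
        x = np.array([0.0, 1.0])
        nb = np.array([2.0, 3.0 + t])
        new = synthesize(x, nb, u)
        # new - x must be parallel to nb - x
        cross = (new - x)[0] * (nb - x)[1] - (new - x)[1] * (nb - x)[0]
        assert abs(cross) < 1e-9


class TestBalanceClasses:
    def test_exact_majority_reaches_three_times_majority(self):
        values, labels = dataset({0: 60, 1: 20, 2: 10})
        out = balance_classes(values, labels, SmoteConfig(seed=1))
        assert out.class_counts() == {0: 60, 1: 60, 2: 60}
        assert len(out.values) == 3 * 60

    def test_already_balanced_input_unchanged(self):
        values, labels = dataset({0: 15, 1: 15, 2: 15})
        out = balance_classes(values, labels, SmoteConfig(seed=1))
        pd.testing.assert_frame_equal(out.values, values)
        assert not out.synthetic.any()

    def test_k_times_mode_synthesizes_k_per_minority_sample(self):
        values, labels = dataset({0: 60, 1: 20, 2: 7})
        out = balance_classes(
            values, labels, SmoteConfig(seed=1, balance_mode="k_times")
        )
        # K = floor(60/20) = 3 and floor(60/7) = 8
        assert out.class_counts() == {0: 60, 1: 20 + 3 * 20, 2: 7 + 8 * 7}

    def test_original_rows_retained_verbatim(self):
        values, labels = dataset({0: 30, 1: 12, 2: 8})
        out = balance_classes(values, labels, SmoteConfig(seed=2))
        pd.testing.assert_frame_equal(out.values.loc[values.index], values)
        assert (~out.synthetic.loc[values.index]).all()

    def test_synthetic_points_lie_on_provenance_segments(self):
        values, labels = dataset({0: 30, 1: 12, 2: 8})
        out = balance_classes(values, labels, SmoteConfig(seed=3))
        for rec in out.provenance.itertuples():
            x = values.loc[rec.base].to_numpy()
            nb = values.loc[rec.neighbor].to_numpy()
            got = out.values.loc[rec.row].to_numpy()
            assert np.allclose(got, x + rec.u * (nb - x))
            # convex combination: between the endpoints coordinate-wise
            assert np.all(got >= np.minimum(x, nb) - 1e-12)
            assert np.all(got <= np.maximum(x, nb) + 1e-12)

    def test_neighbor_provenance_is_a_true_nearest_neighbor(self):
        values, labels = dataset({0: 30, 1: 12, 2: 8}, seed=4)
        cfg = SmoteConfig(seed=4, k_neighbors=5)
        out = balance_classes(values, labels, cfg)
        for rec in out.provenance.itertuples():
            cls = labels.loc[rec.base]
            minority = values[labels == cls]
            base_pos = minority.index.get_loc(rec.base)
            knn = nearest_minority_neighbors(
                base_pos, minority.to_numpy(), cfg.k_neighbors
            )
            assert rec.neighbor in set(minority.index[knn])

    def test_deterministic_given_seed(self):
        values, labels = dataset({0: 25, 1: 10, 2: 7})
        a = balance_classes(values, labels, SmoteConfig(seed=9))
        b = balance_classes(values, labels, SmoteConfig(seed=9))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_minority_smaller_than_k_rejected(self):
        values, labels = dataset({0: 20, 1: 4, 2: 10})
        with pytest.raises(NeighborError):
            balance_classes(values, labels, SmoteConfig(k_neighbors=5))
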