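"""Cleaning stages: missingness filter, winsorisation, imputation,
standardisation, deconfounding — each against a hand or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modecca import (
    Deconfounder,
    NearestNeighbourImputer,
    Winsoriser,
    deconfound,
    exclude_high_missing,
    impute_knn,
    preprocess_phenotypes,
    standardise,
    winsorise,
)
from .conftest import brute_force_knn_impute


class TestMissingnessFilter:
    def test_retains_columns_at_or_below_threshold(self):
        # missing fractions 0.0, 0.1, ..., 0.9 across ten columns
        n = 10
        cols = {}
        for j in range(10):
            col = np.arange(n, dtype=float)
            col[:j] = np.nan
            cols[f"v{j}"] = col
        kept, dropped = exclude_high_missing(pd.DataFrame(cols), 0.5)
        assert kept.shape[1] == 6
        assert dropped == [f"v{j}" for j in range(6, 10)]

    def test_sixty_percent_missing_column_dropped(self):
        df = pd.DataFrame({"a": [1.0] * 10,
                           "b": [np.nan] * 6 + [1.0, 2.0, 3.0, 4.0]})
        kept, dropped = exclude_high_missing(df, 0.5)
        assert dropped == ["b"]

    def test_identity_when_nothing_missing(self):
        df = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        kept, dropped = exclude_high_missing(df, 0.5)
        assert dropped == [] and kept.shape == df.shape

    def test_everything_dropped_is_an_error(self):
        df = pd.DataFrame({"a": [np.nan] * 9 + [1.0]})
        with pytest.raises(ValueError, match="every variable"):
            exclude_high_missing(df, 0.05)


class TestWinsorisation:
    def test_constant_column_unchanged(self):
        df = pd.DataFrame({"c": np.full(50, 3.0)})
        pd.testing.assert_frame_equal(winsorise(df), df)

    def test_bounds_and_interior_on_1_to_200(self):
        x = np.arange(1.0, 201.0)
        out = winsorise(pd.DataFrame({"v": x})).to_numpy().ravel()
        # linear-interpolation percentile oracle, applied by hand
        lo = 1.0 + 0.01 * 199 * 1.0  # rank position 1.99 -> 2.99
        hi = 1.0 + 0.99 * 199 * 1.0
        assert out.min() == pytest.approx(lo)
        assert out.max() == pytest.approx(hi)
        interior = (x > lo) & (x < hi)
        np.testing.assert_array_equal(out[interior], x[interior])

    def test_idempotent_at_fixed_bounds(self, rng):
        df = pd.DataFrame(rng.standard_normal((200, 4)))
        w = Winsoriser().fit(df)
        once = w.transform(df)
        pd.testing.assert_frame_equal(w.transform(once), once)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_clipping_preserves_ranks(self, values):
        df = pd.DataFrame({"v": values})
        out = winsorise(df)["v"]
        ranks_in = df["v"].rank(method="average")
        ranks_out = out.rank(method="average")
        # clipping is monotone: order never inverts (ties may be created)
        pairs = np.sign(np.subtract.outer(out.to_numpy(), out.to_numpy()))
        pairs_in = np.sign(np.subtract.outer(df["v"].to_numpy(),
                                             df["v"].to_numpy()))
        assert not np.any(pairs * pairs_in < 0)

    def test_missing_entries_untouched(self):
        df = pd.DataFrame({"v": [np.nan, 1.0, 2.0, 3.0, 100.0]})
        out = winsorise(df, 10, 90)
        assert np.isnan(out["v"].iloc[0])

    def test_all_missing_column_passes_through_with_warning(self):
        df = pd.DataFrame({"v": [np.nan] * 5, "w": [1.0, 2, 3, 4, 5]})
        with pytest.warns(UserWarning, match="all-missing"):
            out = winsorise(df)
        assert out["v"].isna().all()


class TestImputation:
    def test_identity_without_missing(self, rng):
        df = pd.DataFrame(rng.standard_normal((10, 3)))
        pd.testing.assert_frame_equal(impute_knn(df), df)

    def test_nearest_donor_example(self):
        df = pd.DataFrame([[0.0, 10.0], [0.1, np.nan], [5.0, -3.0]],
                          columns=["c1", "c2"])
        out = impute_knn(df)
        assert out.iloc[1, 1] == 10.0  # A is B's nearest donor on c1

    def test_tie_broken_by_lowest_donor_index(self):
        # donors 0 and 2 equidistant from subject 1
        df = pd.DataFrame([[1.0, 5.0], [0.0, np.nan], [-1.0, 7.0]])
        out1 = impute_knn(df)
        out2 = impute_knn(df)
        assert out1.iloc[1, 1] == 5.0
        pd.testing.assert_frame_equal(out1, out2)

    def test_matches_brute_force_enumeration(self, small_table):
        out = impute_knn(small_table)
        oracle = brute_force_knn_impute(small_table)
        pd.testing.assert_frame_equal(out, oracle)

    def test_observed_cells_unchanged_and_no_missing_left(self, small_table):
        out = impute_knn(small_table)
        assert not out.isna().any().any()
        obs = ~small_table.isna()
        np.testing.assert_array_equal(out.to_numpy()[obs.to_numpy()],
                                      small_table.to_numpy()[obs.to_numpy()])

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="observed value"):
            impute_knn(df)

    def test_k2_averages_two_donors(self):
        df = pd.DataFrame([[0.0, 10.0], [0.05, np.nan], [0.1, 20.0],
                           [9.0, 99.0]])
        out = NearestNeighbourImputer(k=2).fit_transform(df)
        assert out.iloc[1, 1] == pytest.approx(15.0)


class TestStandardisation:
    def test_hand_computed_example_sample_sd(self):
        out = standardise(pd.DataFrame({"v": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(out["v"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)))
        once = standardise(df)
        pd.testing.assert_frame_equal(standardise(once), once)

    def test_means_zero_sds_one(self, rng):
        out = standardise(pd.DataFrame(rng.standard_normal((40, 5)) * 9 + 3))
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-10)

    def test_constant_column_zeroed_and_flagged(self):
        from modecca import Standardiser

        df = pd.DataFrame({"c": [5.0] * 4, "v": [1.0, 2.0, 3.0, 4.0]})
        s = Standardiser().fit(df)
        out = s.transform(df)
        assert (out["c"] == 0).all()
        assert s.zero_variance_columns_ == ["c"]


class TestDeconfounding:
    def test_pure_confound_column_residual_is_zero(self, rng):
        conf = pd.DataFrame({"a": rng.standard_normal(30)})
        df = pd.DataFrame({"v": 2.0 * conf["a"]})
        out = deconfound(df, conf)
        np.testing.assert_allclose(out["v"], 0.0, atol=1e-10)

    def test_orthogonal_column_only_mean_centred(self):
        conf = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0]})
        df = pd.DataFrame({"v": [1.0, 1.0, -1.0, -1.0]})  # orthogonal to a
        out = deconfound(df, conf)
        np.testing.assert_allclose(out["v"], df["v"] - df["v"].mean(),
                                   atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = pd.DataFrame(rng.standard_normal((50, 4)))
        conf = pd.DataFrame(rng.standard_normal((50, 3)))
        out = deconfound(x, conf)
        d = np.column_stack([np.ones(50), conf.to_numpy()])
        beta = np.linalg.solve(d.T @ d, d.T @ x.to_numpy())
        np.testing.assert_allclose(out.to_numpy(), x.to_numpy() - d @ beta,
                                   atol=1e-8)

    def test_residuals_uncorrelated_with_confounds(self, rng):
        x = pd.DataFrame(rng.standard_normal((100, 6)))
        conf = pd.DataFrame(rng.standard_normal((100, 3)),
                            columns=["a", "b", "c"])
        out = deconfound(x, conf)
        for c in conf:
            corr = out.apply(lambda col: np.corrcoef(col, conf[c])[0, 1])
            assert (corr.abs() <= 1e-8).all()

    def test_projection_idempotence(self, rng):
        x = pd.DataFrame(rng.standard_normal((60, 3)))
        conf = pd.DataFrame(rng.standard_normal((60, 2)))
        once = deconfound(x, conf)
        np.testing.assert_allclose(deconfound(once, conf).to_numpy(),
                                   once.to_numpy(), atol=1e-10)

    def test_rank_deficient_confounds_dropped_and_logged(self, rng):
        a = rng.standard_normal(40)
        conf = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.standard_normal(40)})
        dec = Deconfounder().fit(pd.DataFrame(rng.standard_normal((40, 2))),
                                 confounds=conf)
        assert dec.dropped_confounds_  # one of the collinear pair was dropped

    def test_incomplete_confounds_rejected(self):
        conf = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="complete"):
            deconfound(pd.DataFrame({"v": [1.0, 2.0, 3.0]}), conf)


class TestPhenotypeRecipe:
    def test_order_and_no_missing_after(self, rng):
        vals = rng.standard_normal((60, 6))
        vals[rng.random((60, 6)) < 0.2] = np.nan
        vals[:45, 5] = np.nan  # 75% missing -> excluded
        df = pd.DataFrame(vals, columns=[f"v{j}" for j in range(6)])
        conf = pd.DataFrame(rng.standard_normal((60, 2)), columns=["a", "b"])
        out, log = preprocess_phenotypes(df, conf)
        assert log["order"] == ["filter", "winsorise", "impute",
                                "standardise", "deconfound"]
        assert log["dropped_columns"] == ["v5"]
        assert not out.isna().any().any()
        for c in conf:
            corr = out.apply(lambda col: np.corrcoef(col, conf[c])[0, 1])
            assert (corr.abs() <= 1e-8).all()
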