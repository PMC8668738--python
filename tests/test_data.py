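import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irakit import (
    AlignmentError,
    AnnualMatrix,
    DataError,
    SeriesVector,
    compute_lpuc,
    distance_correlation,
    lag_series,
    prune_correlated,
    quintile_categorize,
    standardize,
)

from conftest import make_matrix, make_series


def brute_force_dcor(x, y):
    """Independent O(n^2) double-centering implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    dvx, dvy = (A * A).mean(), (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy))


class TestLpuc:
    def test_direct_ratio(self):
        landings = make_matrix([[1000.0], [1500.0], [900.0]], names=["taxonA"])
        capacity = make_series([500.0, 500.0, 300.0], label="gt")
        lpuc = compute_lpuc(landings, capacity)
        assert lpuc.frame.iloc[0, 0] == 2.0
        assert lpuc.frame.iloc[2, 0] == 3.0

    def test_fleet_aggregation_sums_before_ratio(self):
        # two fleets: landings 800 + 200 kg over capacities 300 + 200 GT
        landings = make_matrix(np.full((3, 1), 800.0 + 200.0), names=["taxonA"])
        capacity = make_series(np.full(3, 300.0 + 200.0), label="gt")
        assert compute_lpuc(landings, capacity).frame.iloc[0, 0] == 2.0

    def test_zero_capacity_rejected(self):
        landings = make_matrix(np.ones((3, 1)))
        capacity = make_series([1.0, 0.0, 2.0])
        with pytest.raises(DataError):
            compute_lpuc(landings, capacity)

    def test_year_mismatch_rejected(self):
        landings = make_matrix(np.ones((3, 1)), start=2000)
        capacity = make_series(np.ones(3), start=2001)
        with pytest.raises(AlignmentError):
            compute_lpuc(landings, capacity)

    def test_multiplying_back_recovers_landings(self):
        rng = np.random.default_rng(5)
        landings = make_matrix(rng.uniform(10, 1000, (6, 3)))
        capacity = make_series(rng.uniform(100, 500, 6))
        lpuc = compute_lpuc(landings, capacity)
        back = lpuc.frame.mul(capacity.values, axis=0)
        assert np.allclose(back.to_numpy(), landings.values, rtol=1e-14, atol=0)


class TestStandardize:
    def test_simple_column(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]))
        out = standardize(m)
        assert np.allclose(out.values.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_column_rejected_by_name(self):
        m = make_matrix(np.column_stack([np.arange(4.0), np.full(4, 7.0)]),
                        names=["ok", "flat"])
        with pytest.raises(DataError, match="flat"):
            standardize(m)

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(5, 3, (20, 4)))
        z = standardize(m)
        assert np.allclose(z.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.values.std(axis=0, ddof=1), 1, atol=1e-12)
        z2 = standardize(z)
        assert np.allclose(z2.values, z.values, atol=1e-10)


class TestLag:
    def test_identity_and_shift(self):
        s = make_series([1.0, 2.0, 3.0], start=1966)
        assert lag_series(s, 0) is s
        lagged = lag_series(s, 1)
        assert lagged.years.tolist() == [1967, 1968]
        assert lagged.values.tolist() == [1.0, 2.0]

    def test_length_bookkeeping(self):
        s = make_series(np.arange(52.0), start=1966)
        assert len(lag_series(s, 2)) == 50

    def test_excessive_lag_rejected(self):
        with pytest.raises(DataError):
            lag_series(make_series([1.0, 2.0, 3.0]), 3)


class TestDistanceCorrelation:
    def test_affine_dependence_is_one(self):
        rng = np.random.default_rng(1)
        x = make_series(rng.normal(size=10))
        y = make_series(2 * x.values + 3)
        assert distance_correlation(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_independent_draws_near_zero(self):
        rng = np.random.default_rng(42)
        x = make_series(rng.normal(size=500))
        y = make_series(rng.normal(size=500))
        assert distance_correlation(x, y) < 0.15

    def test_matches_brute_force_oracle(self):
        x = make_series([0.0, 1.0, 2.0, 3.0])
        y = make_series([0.0, 1.0, 0.0, 1.0])
        assert distance_correlation(x, y) == pytest.approx(
            brute_force_dcor(x.values, y.values), abs=1e-10
        )
        rng = np.random.default_rng(7)
        for _ in range(3):
            xv, yv = rng.normal(size=20), rng.normal(size=20)
            got = distance_correlation(make_series(xv), make_series(yv))
            assert got == pytest.approx(brute_force_dcor(xv, yv), abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=20, unique=True),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    def test_symmetry_and_affine_invariance(self, vals, a, b):
        rng = np.random.default_rng(len(vals))
        x = make_series(vals)
        y = make_series(rng.normal(size=len(vals)))
        d1 = distance_correlation(x, y)
        assert distance_correlation(y, x) == pytest.approx(d1, abs=1e-8)
        xt = make_series(a * np.asarray(vals) + b)
        assert distance_correlation(xt, y) == pytest.approx(d1, abs=1e-8)


class TestPrune:
    def test_duplicate_dropped(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=12)
        m = make_matrix(np.column_stack([a, a]), names=["a", "dup"])
        kept, report = prune_correlated(m, threshold=0.95)
        assert kept.variables == ["a"]
        assert report[0].dropped == "dup" and report[0].kept == "a"

    def test_independent_noise_kept(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(40, 4)))
        kept, report = prune_correlated(m, threshold=0.95)
        assert kept.variables == m.variables and report == []

    def test_exact_copy_with_independent_middle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        m = make_matrix(np.column_stack([a, b, a]), names=["A", "B", "C"])
        kept, report = prune_correlated(m, threshold=0.9)
        assert kept.variables == ["A", "B"]
        assert report[0].dropped == "C" and report[0].dcor == pytest.approx(1.0)


class TestQuintiles:
    def test_even_split(self):
        m = make_matrix(np.arange(1.0, 11.0)[:, None], names=["v"])
        cm = quintile_categorize(m, ["v"])
        assert cm.frame.loc["v"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_gets_lowest_code(self):
        m = make_matrix(np.full((6, 1), 3.3), names=["v"])
        cm = quintile_categorize(m, ["v"])
        assert set(cm.frame.loc["v"]) == {1}

    def test_rows_follow_loading_order(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 2)),
                        names=["a", "b"])
        cm = quintile_categorize(m, ["b", "a"])
        assert cm.variables == ["b", "a"]

    def test_codes_partition_each_column(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(25, 3)))
        cm = quintile_categorize(m, m.variables)
        for v in m.variables:
            codes = cm.frame.loc[v].to_numpy()
            assert codes.min() >= 1 and codes.max() <= 5
            counts = np.bincount(codes, minlength=6)[1:]
            assert counts.max() - counts.min() <= 1


class TestIO:
    def test_csv_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(8, 3)), start=1966)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        m.to_csv(p1)
        m2 = AnnualMatrix.read_csv(p1)
        m2.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert m2 == m

    def test_gaps_rejected(self):
        years = np.array([2000, 2001, 2003])
        with pytest.raises(DataError):
            AnnualMatrix(pd.DataFrame(np.ones((3, 1)), index=years, columns=["v"]))

    def test_missing_cells_rejected(self):
        df = pd.DataFrame(np.ones((3, 1)), index=[2000, 2001, 2002], columns=["v"])
        df.iloc[1, 0] = np.nan
        with pytest.raises(DataError):
            AnnualMatrix(df)
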