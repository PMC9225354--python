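import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from imatct import (
    PowerSpec, pearson, linear_regression, two_sample_t, sample_size_normal,
    correlation_table, generate_cohort, CohortSpec,
)
from oracles import exhaustive_permutation_t_pvalue


def _data_with_exact_r(r, n=30, seed=0):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (z @ x) / (x @ x)  # orthogonalise
    z /= z.std()
    y = r * x + np.sqrt(1 - r * r) * z
    return x, y


class TestPearson:
    def test_exact_linearity(self):
        res = pearson([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_squared_is_square_of_r(self):
        x, y = _data_with_exact_r(0.898)
        res = pearson(x, y)
        assert res.r == pytest.approx(0.898, abs=1e-12)
        assert round(res.r_squared, 3) == 0.806

    def test_pair_order_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        perm = rng.permutation(20)
        assert pearson(x, y).r == pytest.approx(pearson(x[perm], y[perm]).r)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate|variance"):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_invariant_under_positive_affine_maps(self, scale, shift):
        x, y = _data_with_exact_r(0.5, seed=3)
        base = pearson(x, y).r
        assert pearson(scale * x + shift, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(-scale * x + shift, y).r == pytest.approx(-base, abs=1e-12)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = linear_regression(x, 3 * x + 1)
        assert (slope, intercept, r2) == (pytest.approx(3.0), pytest.approx(1.0),
                                          pytest.approx(1.0))

    def test_r_squared_identity_with_pearson(self, rng):
        x = rng.normal(size=50)
        y = 2 * x + rng.normal(size=50)
        _, _, r2 = linear_regression(x, y)
        assert r2 == pytest.approx(pearson(x, y).r_squared, abs=1e-12)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1, 2, 3], [5, 5, 5])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)
        assert res.df == 4

    def test_large_separation_is_significant(self, rng):
        a = rng.normal(0, 0.01, size=8)
        b = rng.normal(10, 0.01, size=8)
        assert two_sample_t(a, b).p_two_tailed < 0.001

    def test_agrees_with_exhaustive_permutation_oracle(self):
        # sham-vs-treated style 4 vs 4 fixture; C(8,4) = 70 relabelings
        a = [4.3, 3.6, 2.1, 3.9]
        b = [5.6, 4.3, 4.6, 3.7]
        res = two_sample_t(a, b)
        p_perm = exhaustive_permutation_t_pvalue(a, b)
        assert abs(res.p_two_tailed - p_perm) <= 0.02

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestSampleSize:
    def test_study_design_case(self):
        # 30% difference, 15% SD, 80% power at alpha 5% -> 4 per group
        assert sample_size_normal(PowerSpec(delta=30, sd=15)) == 4

    def test_rule_of_thumb_at_unit_effect(self):
        assert sample_size_normal(PowerSpec(delta=15, sd=15)) == 16

    def test_monotone_in_delta_and_power(self):
        n_small = sample_size_normal(PowerSpec(delta=10, sd=15))
        n_large = sample_size_normal(PowerSpec(delta=20, sd=15))
        assert n_large <= n_small
        n_lo = sample_size_normal(PowerSpec(delta=15, sd=15, power=0.7))
        n_hi = sample_size_normal(PowerSpec(delta=15, sd=15, power=0.9))
        assert n_hi >= n_lo

    def test_exact_noncentral_t_never_smaller(self):
        spec = PowerSpec(delta=30, sd=15)
        assert sample_size_normal(spec, exact=True) >= sample_size_normal(spec)

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            PowerSpec(delta=30, sd=15, power=1.0)


class TestCorrelationTable:
    @pytest.fixture()
    def cohort(self):
        return generate_cohort(CohortSpec(n_subjects=60, rng_seed=21))

    def test_one_row_per_requested_pair_with_consistent_flags(self, cohort):
        pairs = [("age", "MD"), ("age", "IMAT_pct"), ("MD", "IMAT_pct")]
        table = correlation_table(cohort, cohort[["subject_id"]], pairs)
        assert len(table) == len(pairs)
        for _, row in table.iterrows():
            recomputed = pearson(cohort[row["x"]], cohort[row["y"]])
            assert row["p"] == pytest.approx(recomputed.p_two_tailed)
            expected = "**" if row["p"] < 0.01 else ("*" if row["p"] < 0.05 else "")
            assert row["flag"] == expected

    def test_noiseless_cohort_gives_unit_correlations(self):
        spec = CohortSpec(n_subjects=50, rng_seed=1,
                          noise_sds={"md": 0.0, "imat_pct": 0.0, "mv": 0.0,
                                     "rise_time": 0.0, "strength": 0.0})
        df = generate_cohort(spec)
        table = correlation_table(df, df[["subject_id"]],
                                  [("age", "MD"), ("age", "IMAT_pct")])
        assert np.allclose(np.abs(table["r"]), 1.0)

    def test_disjoint_keys_rejected(self, cohort):
        other = pd.DataFrame({"subject_id": [10_000], "y": [1.0]})
        with pytest.raises(ValueError, match="shared"):
            correlation_table(cohort, other, [("age", "y")])
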