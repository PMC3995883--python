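import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from normscreen import (CohortSpec, GroupSpec, RegressionSpec, RetestSpec,
                        fit_norm_regression, generate_cohort, write_cohort)
from normscreen.errors import FeasibilityError
from normscreen.simulate import (ZeroInflatedMarginal, mmse_coupling,
                                 score_marginal, solve_truncnorm)

from conftest import mci_group, nc_group


def truncated_moments_by_quadrature(mu, sigma, lo=0.0, hi=56.0):
    """Independent oracle: mean/SD of a normal(mu, sigma) conditioned on
    [lo, hi], by numerical integration of the renormalised density."""
    norm_pdf = lambda x: math.exp(-0.5 * ((x - mu) / sigma) ** 2) / (
        sigma * math.sqrt(2 * math.pi))
    mass, _ = quad(norm_pdf, lo, hi, limit=200)
    m1, _ = quad(lambda x: x * norm_pdf(x), lo, hi, limit=200)
    m2, _ = quad(lambda x: x * x * norm_pdf(x), lo, hi, limit=200)
    mean = m1 / mass
    var = m2 / mass - mean ** 2
    return mean, math.sqrt(var)


class TestSolveTruncnorm:
    def test_symmetric_target_far_from_bounds(self):
        mu, sigma = solve_truncnorm(28.0, 2.0)
        assert mu == pytest.approx(28.0, abs=1e-4)
        assert sigma == pytest.approx(2.0, abs=1e-4)

    @pytest.mark.parametrize("mean, sd", [
        (26.60, 8.49),     # control-like
        (9.40, 8.88),      # highly skewed, near the exponential frontier
        (13.91, 8.79),
        (30.03, 8.58),
    ])
    def test_matches_quadrature_oracle(self, mean, sd):
        mu, sigma = solve_truncnorm(mean, sd)
        q_mean, q_sd = truncated_moments_by_quadrature(mu, sigma)
        assert q_mean == pytest.approx(mean, abs=1e-6)
        assert q_sd == pytest.approx(sd, abs=1e-6)

    def test_skewed_target_needs_latent_mean_below_target(self):
        mu, _ = solve_truncnorm(9.40, 8.88)
        assert mu < 9.40

    def test_sd_beyond_half_range_is_infeasible(self):
        with pytest.raises(FeasibilityError):
            solve_truncnorm(28.0, 40.0)

    def test_floor_effect_moments_are_infeasible(self):
        # SD > mean next to the floor: beyond the log-concave frontier
        with pytest.raises(FeasibilityError):
            solve_truncnorm(1.60, 4.58)

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(FeasibilityError):
            solve_truncnorm(60.0, 5.0)


class TestScoreMarginal:
    def test_floor_effect_falls_back_to_zero_inflated(self):
        marg = score_marginal(1.60, 4.58)
        assert isinstance(marg, ZeroInflatedMarginal)

    @pytest.mark.parametrize("mean, sd", [(1.60, 4.58), (4.02, 6.06)])
    def test_zero_inflated_moments_match(self, mean, sd):
        marg = score_marginal(mean, sd)
        rng = np.random.default_rng(11)
        x = marg.ppf(rng.random(1_000_000))
        se_mean = sd / 1000.0
        assert x.mean() == pytest.approx(mean, abs=3 * se_mean)
        assert x.std() == pytest.approx(sd, rel=0.01)

    def test_large_sample_truncnorm_moments_within_monte_carlo_error(self):
        n = 100_000
        marg = score_marginal(9.40, 8.88)
        rng = np.random.default_rng(5)
        x = marg.ppf(rng.random(n))   # pre-rounding draws
        assert x.mean() == pytest.approx(9.40, abs=3 * 8.88 / math.sqrt(n))
        assert x.std() == pytest.approx(8.88, rel=0.02)


class TestGenerateCohort:
    def test_same_seed_byte_identical_csv(self, tmp_path):
        spec = CohortSpec(groups=[nc_group(n=50), mci_group(n=30)], seed=9)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(generate_cohort(spec), p1)
        write_cohort(generate_cohort(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        spec = CohortSpec(groups=[nc_group(n=50)], seed=9)
        a = generate_cohort(spec, seed=1).to_frame()
        b = generate_cohort(spec, seed=2).to_frame()
        assert not a.equals(b)

    def test_appending_a_group_preserves_existing_streams(self):
        base = CohortSpec(groups=[nc_group(n=40), mci_group(n=30)], seed=13)
        extended = CohortSpec(
            groups=[nc_group(n=40), mci_group(n=30),
                    mci_group(n=10, label="AD", dsr_mean=1.6, dsr_sd=4.58)],
            seed=13)
        a = generate_cohort(base).to_frame()
        b = generate_cohort(extended).to_frame()
        cols = [c for c in a.columns if c != "mmse"]
        # mmse loading is recalibrated when the group mix changes;
        # all other per-subject draws must be untouched
        assert a[cols].equals(b[b.group.isin(["NC", "MCI"])][cols]
                              .reset_index(drop=True))

    def test_moment_recovery_at_n_10000(self):
        spec = CohortSpec(groups=[nc_group(n=10000)], seed=21)
        df = generate_cohort(spec).to_frame()
        assert df.dsr.mean() == pytest.approx(26.60, abs=0.3)
        assert df.dsr.std() == pytest.approx(8.49, abs=0.3)
        assert df.isr.mean() == pytest.approx(30.03, abs=0.3)

    def test_all_scores_within_bounds(self, cohort):
        df = cohort.to_frame()
        assert df.dsr.between(0, 56).all()
        assert df.isr.between(0, 56).all()
        assert df.mmse.between(0, 30).all()
        retests = df.dsr_retest.dropna()
        assert retests.between(0, 56).all()

    def test_zero_noise_degenerates_to_regression_line(self):
        spec = CohortSpec(
            groups=[nc_group(n=25, age_mean=65, age_sd=0, edu_mean=13,
                             edu_sd=0)],
            nc_regression=RegressionSpec(31.535, 0.746, -0.206, 0.0),
            seed=2)
        df = generate_cohort(spec).to_frame()
        line = 31.535 + 0.746 * 13 - 0.206 * 65
        assert df.dsr.nunique() == 1
        assert df.dsr.iloc[0] == pytest.approx(line, abs=0.5)  # integer rounding

    def test_regression_coefficients_recovered_on_large_cohort(
            self, nc_cohort_large):
        fit = fit_norm_regression(nc_cohort_large)
        assert fit.beta_edu == pytest.approx(0.746, abs=3 * fit.se_beta_edu)
        assert fit.beta_age == pytest.approx(-0.206, abs=3 * fit.se_beta_age)

    def test_retest_subset_size_and_correlation(self, cohort):
        retested = [r for r in cohort if r.dsr_retest is not None]
        assert len(retested) == 56
        assert all(r.group == "MCI" for r in retested)


def test_single_group_partial_correlation_target_recovered():
    from normscreen import partial_corr
    spec = CohortSpec(groups=[nc_group(n=20000)], mmse_dsr_partial_r=0.4,
                      seed=0)
    df = generate_cohort(spec).to_frame()
    r = partial_corr(df.mmse, df.dsr,
                     np.column_stack([df.age, df.education_years])).r
    assert r == pytest.approx(0.4, abs=0.03)


def test_infeasible_group_spec_propagates():
    with pytest.raises(Exception):
        GroupSpec(label="bad", n=10, age_mean=70, age_sd=5, edu_mean=10,
                  edu_sd=3, isr_mean=60.0, isr_sd=5, dsr_mean=20, dsr_sd=5,
                  mmse_mean=25, mmse_sd=2)
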