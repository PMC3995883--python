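import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normscreen import (Band, build_norm_table, default_bands, norms_frame,
                        percentile, petersen_cutoff)
from normscreen.cohort import CohortTable
from normscreen.errors import ValidationError

from conftest import make_record


def percentile_oracle(values, p):
    """Brute-force (n+1)p weighted-average estimator: sort, take the
    fractional position h = (n+1)p/100, interpolate linearly."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    h = (n + 1) * p / 100.0
    if h <= 1:
        return x[0]
    if h >= n:
        return x[-1]
    k = int(np.floor(h))
    frac = h - k
    return x[k - 1] + frac * (x[k] - x[k - 1])


class TestPercentile:
    def test_hand_evaluated_position(self):
        # h = 101 * 0.05 = 5.05 -> between the 5th and 6th order stats
        assert percentile(np.arange(1, 101), 5) == pytest.approx(5.05)
        assert percentile(np.arange(1, 101), 10) == pytest.approx(10.1)

    @given(st.lists(st.floats(0, 56), min_size=2, max_size=40),
           st.sampled_from([5, 10, 25, 50, 75, 90]))
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, values, p):
        assert percentile(values, p) == pytest.approx(
            percentile_oracle(values, p), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            percentile([], 5)


class TestPetersenCutoff:
    @pytest.mark.parametrize("mean, sd, raw, one_dp", [
        (28.10, 8.54, 15.29, 15.3),
        (26.22, 8.92, 12.84, 12.8),
        (24.42, 8.90, 11.07, 11.1),
    ])
    def test_normative_strata(self, mean, sd, raw, one_dp):
        cut = petersen_cutoff(mean, sd)
        assert cut == pytest.approx(raw, abs=0.005)
        assert round(cut, 1) == one_dp

    def test_zero_sd_identity(self):
        assert petersen_cutoff(20.0, 0.0) == 20.0

    @given(st.floats(-5, 60), st.floats(0, 20), st.floats(-10, 10))
    @settings(max_examples=100, derandomize=True)
    def test_linear_in_the_mean(self, mean, sd, shift):
        lhs = petersen_cutoff(mean + shift, sd)
        rhs = petersen_cutoff(mean, sd) + shift
        assert lhs == pytest.approx(rhs, abs=1e-9)


def _toy_cohort():
    recs = []
    scores = [(55, 10), (58, 20), (60, 30),        # 50-64, edu 12
              (70, 15), (72, 25),                  # 65-74, edu 6
              (80, 18)]                            # 75-85
    for i, (age, dsr) in enumerate(scores):
        edu = 6 if 65 <= age <= 74 else 12
        level = "primary" if edu == 6 else "middle"
        recs.append(make_record(id=f"T{i}", age=float(age),
                                education_years=float(edu),
                                education_level=level, dsr=dsr,
                                isr=dsr + 10))
    return CohortTable(recs)


class TestBuildNormTable:
    def test_hand_arithmetic_cell(self):
        cells = build_norm_table(_toy_cohort(), [Band(50, 64, "all")])
        dsr = next(c for c in cells if c.measure == "DSR")
        assert dsr.n == 3
        assert dsr.mean == pytest.approx(20.0)
        assert dsr.sd == pytest.approx(10.0)

    def test_empty_cell_emitted_with_zero_n(self):
        cells = build_norm_table(_toy_cohort(), [Band(40, 45, "all")])
        assert all(c.n == 0 and c.mean is None for c in cells)

    def test_single_subject_cell_has_no_sd(self):
        cells = build_norm_table(_toy_cohort(), [Band(75, 85, "all")])
        dsr = next(c for c in cells if c.measure == "DSR")
        assert dsr.n == 1 and dsr.sd is None and dsr.flags

    def test_education_strata_partition_each_age_band(self, cohort):
        cells = build_norm_table(cohort)
        by = {(c.band.label(), c.measure): c for c in cells}
        for lo, hi in ((50, 64), (65, 74), (75, 85)):
            total = by[(f"{lo}-{hi}/all", "DSR")].n
            parts = (by[(f"{lo}-{hi}/edu<=9", "DSR")].n
                     + by[(f"{lo}-{hi}/edu>9", "DSR")].n)
            assert parts == total

    def test_percentiles_respect_ordering(self, cohort):
        for c in build_norm_table(cohort):
            if c.n >= 2:
                assert c.p5 <= c.p10 <= c.mean + 3 * c.sd

    def test_norm_structure_tracks_age_gradient(self, nc_cohort_large):
        """Older strata should norm lower, consistent with the published
        age-band means (50-64: 28.10, 65-74: 26.22, 75-85: 24.42); the
        generator's independent age/education draws reproduce the
        gradient to within a couple of score points."""
        cells = {c.band.label(): c for c in build_norm_table(nc_cohort_large)
                 if c.measure == "DSR"}
        m1 = cells["50-64/all"].mean
        m2 = cells["65-74/all"].mean
        m3 = cells["75-85/all"].mean
        assert m1 > m2 > m3
        assert m1 == pytest.approx(28.10, abs=2.0)
        assert m2 == pytest.approx(26.22, abs=2.0)
        assert m3 == pytest.approx(24.42, abs=2.0)

    def test_retention_in_plausible_range(self, cohort):
        for c in build_norm_table(cohort):
            if c.n >= 5:
                assert 60 < c.retention_pct < 110

    def test_norms_frame_layout(self, cohort):
        df = norms_frame(build_norm_table(cohort))
        assert len(df) == 18    # 9 strata x 2 measures
        assert {"stratum", "measure", "n", "mean", "sd", "p5", "p10",
                "retention_pct", "petersen_cutoff"} <= set(df.columns)
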