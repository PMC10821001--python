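"""Age binning and per-bin summary statistics."""

import math

import numpy as np
import pytest

from dosecurve import (
    AgeBinScheme,
    CohortConfig,
    DoseRecord,
    ValidationError,
    assign_bin,
    generate_cohort,
    integer_age,
    ratio_profile,
    summarize,
)


class TestIntegerAge:
    @pytest.mark.parametrize("age, expected", [(2.5, 2), (0.99, 0), (14.999, 14), (7, 7)])
    def test_floor_convention(self, age, expected):
        assert integer_age(age) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            integer_age(-0.5)


class TestAssignBin:
    def test_drl_groups(self):
        scheme = AgeBinScheme.drl_group()
        assert assign_bin(0.9, scheme) == "0"
        assert assign_bin(4.9, scheme) == "1-4"   # floor(4.9) = 4
        assert assign_bin(5.0, scheme) == "5-9"
        assert assign_bin(14.999, scheme) == "10-14"

    def test_phantom_bins_half_open(self):
        scheme = AgeBinScheme.phantom_bin()
        assert assign_bin(0.5, scheme) == "0.5-2.5"
        assert assign_bin(2.49, scheme) == "0.5-2.5"

    def test_age_beyond_coverage_rejected(self):
        with pytest.raises(ValidationError):
            assign_bin(15.0, AgeBinScheme.integer_year())

    def test_partition_is_exhaustive_and_unique(self):
        """Every age maps to exactly one bin in every scheme."""
        rng = np.random.default_rng(7)
        ages = rng.uniform(0, 15, size=500)
        for scheme in (
            AgeBinScheme.integer_year(),
            AgeBinScheme.drl_group(),
            AgeBinScheme.phantom_bin(),
        ):
            labels = [assign_bin(a, scheme) for a in ages]
            assert set(labels) <= set(scheme.labels)
            # by-hand containment check for uniqueness
            for age, label in zip(ages, labels):
                lo, hi = {lab: (lo, hi) for lab, lo, hi in scheme.bins}[label]
                key = integer_age(age) if scheme.kind in ("integer_year", "drl_group") else age
                assert lo <= key < hi

    def test_malformed_scheme_rejected(self):
        with pytest.raises(ValidationError):
            AgeBinScheme.custom((("a", 0.0, 5.0), ("b", 6.0, 15.0)))  # gap


class TestSummarize:
    def test_median_conventions(self):
        scheme = AgeBinScheme.drl_group()
        odd = summarize([2, 2.5, 3], [1, 2, 3], scheme)
        assert odd.set_index("bin").loc["1-4", "median"] == 2
        assert odd.set_index("bin").loc["1-4", "mean"] == 2
        even = summarize([2, 2.5, 3, 4], [1, 2, 3, 4], scheme)
        assert even.set_index("bin").loc["1-4", "median"] == 2.5

    def test_sd_uses_n_minus_one(self):
        scheme = AgeBinScheme.drl_group()
        frame = summarize([6, 7], [2.0, 4.0], scheme).set_index("bin")
        assert frame.loc["5-9", "sd"] == pytest.approx(math.sqrt(2))
        assert frame.loc["5-9", "cv_percent"] == pytest.approx(100 * math.sqrt(2) / 3)

    def test_single_record_has_zero_sd_and_cv(self):
        frame = summarize([1.5], [3.0], AgeBinScheme.drl_group()).set_index("bin")
        assert frame.loc["1-4", "n"] == 1
        assert frame.loc["1-4", "sd"] == 0.0
        assert frame.loc["1-4", "cv_percent"] == 0.0

    def test_empty_bins_reported_with_zero_n(self):
        frame = summarize([0.5], [100.0], AgeBinScheme.integer_year())
        assert len(frame) == 15
        assert frame["n"].sum() == 1
        assert frame.loc[frame["bin"] == "3", "n"].item() == 0
        assert np.isnan(frame.loc[frame["bin"] == "3", "median"].item())

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(11)
        ages = rng.uniform(0, 15, size=200)
        values = rng.uniform(1, 2, size=200)
        for scheme in (AgeBinScheme.integer_year(), AgeBinScheme.drl_group()):
            assert summarize(ages, values, scheme)["n"].sum() == 200


class TestRatioProfile:
    def test_noiseless_ratios_have_zero_cv(self):
        config = CohortConfig(dlp_noise_cv=0.0, device_noise_cv=0.0, seed=3)
        records = generate_cohort(config)
        frame = ratio_profile(records, AgeBinScheme.phantom_bin())
        expected = [ratio for _, _, ratio in config.device_bins.bins]
        assert frame["mean"].to_numpy() == pytest.approx(expected, rel=1e-9)
        assert (frame["cv_percent"].abs() < 1e-6).all()

    def test_two_percent_noise_gives_two_percent_cv(self):
        """Per-bin CV of the device ratio tracks the generator's noise CV."""
        config = CohortConfig(device_noise_cv=0.02, dlp_noise_cv=0.0, seed=5)
        records = generate_cohort(config)
        frame = ratio_profile(records, AgeBinScheme.phantom_bin())
        populated = frame[frame["n"] >= 50]
        assert not populated.empty
        assert populated["cv_percent"].to_numpy() == pytest.approx(2.0, abs=0.5)

    def test_records_without_device_ed_are_excluded(self):
        records = [
            DoseRecord(exam_id="A", age_years=3.0, dlp=500.0, device_ed=2.35),
            DoseRecord(exam_id="B", age_years=3.2, dlp=520.0),
        ]
        frame = ratio_profile(records, AgeBinScheme.phantom_bin())
        assert frame["n"].sum() == 1

    def test_no_eligible_records_yields_empty_summary(self):
        records = [DoseRecord(exam_id="B", age_years=3.2, dlp=520.0)]
        frame = ratio_profile(records, AgeBinScheme.phantom_bin())
        assert (frame["n"] == 0).all()

    def test_records_spanning_two_bins_yield_two_rows(self):
        records = [
            DoseRecord(exam_id="A", age_years=1.0, dlp=500.0, device_ed=3.8),
            DoseRecord(exam_id="B", age_years=4.0, dlp=600.0, device_ed=2.82),
        ]
        frame = ratio_profile(records, AgeBinScheme.phantom_bin())
        assert (frame["n"] > 0).sum() == 2
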