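"""Dose-interval construction, treatment-day sampling, and AE-per-word rates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosewords import (
    BinningScheme,
    DoseBin,
    count_ae_mentions,
    define_ae_intervals,
    estimate_rate,
    load_ae_dictionary,
    sample_treatment_days,
)
from dosewords.ae import AEInterval
from dosewords.errors import ConfigurationError, InsufficientDataError, UndefinedRateError

from conftest import make_notes


def dummy_bins(indices, width=0.5):
    return [
        DoseBin(
            method="ddd", subset="all", index=k, lower=(k - 1) * width,
            upper=k * width, patient_means={f"p{i}": 1.0 for i in range(10)},
            median_words=1.0,
        )
        for k in indices
    ]


def make_exposures(n_days, doses, pid="p1"):
    dates = pd.date_range("2005-01-01", periods=n_days)
    return pd.DataFrame(
        {
            "patient_id": pid,
            "date": dates,
            "equivalent_dose": doses,
            "convertible": True,
        }
    )


class TestDefineIntervals:
    def test_nine_bins_split_into_equal_thirds(self):
        scheme = BinningScheme(method="ddd", width=0.5)
        low, mid, high = define_ae_intervals(dummy_bins(range(1, 10)), scheme)
        assert (low.lower, low.upper) == (0.0, 1.5)
        assert (mid.lower, mid.upper) == (1.5, 3.0)
        assert (high.lower, high.upper) == (3.0, 4.5)
        assert low.bin_indices == (1, 2, 3)
        assert high.bin_indices == (7, 8, 9)

    def test_span_rounds_up_to_multiple_of_three_bins(self):
        scheme = BinningScheme(method="ddd", width=0.5)
        low, mid, high = define_ae_intervals(dummy_bins([1, 4, 7]), scheme)
        # k_max=7 -> 9 bins total, 3 per interval
        assert high.upper == pytest.approx(4.5)
        assert [len(iv.bin_indices) for iv in (low, mid, high)] == [3, 3, 3]

    def test_intervals_are_contiguous_and_equal_width(self):
        scheme = BinningScheme(method="olanzapine_eq", width=5.0)
        ivs = define_ae_intervals(dummy_bins(range(1, 8), width=5.0), scheme)
        widths = {iv.upper - iv.lower for iv in ivs}
        assert len(widths) == 1
        assert ivs[0].upper == ivs[1].lower and ivs[1].upper == ivs[2].lower

    def test_too_narrow_span_is_insufficient(self):
        scheme = BinningScheme(method="ddd", width=0.5)
        with pytest.raises(InsufficientDataError):
            define_ae_intervals(dummy_bins([1, 2]), scheme)
        with pytest.raises(InsufficientDataError):
            define_ae_intervals([], scheme)


class TestSampling:
    interval = AEInterval(method="ddd", label="low", lower=0.0, upper=1.5,
                          bin_indices=(1, 2, 3))

    def test_exactly_n_qualifying_days_all_selected(self):
        expo = make_exposures(125, 1.0)
        days = sample_treatment_days(self.interval, expo, n=125, seed=0)
        assert len(days) == 125

    def test_fewer_than_n_warns_and_returns_all(self):
        expo = make_exposures(30, 1.0)
        with pytest.warns(UserWarning):
            days = sample_treatment_days(self.interval, expo, n=125, seed=0)
        assert len(days) == 30

    def test_same_seed_same_sample(self):
        expo = make_exposures(500, 1.0)
        a = sample_treatment_days(self.interval, expo, n=125, seed=42)
        b = sample_treatment_days(self.interval, expo, n=125, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_sample_respects_interval_bounds(self):
        doses = np.linspace(0.1, 4.0, 400)
        expo = make_exposures(400, doses)
        days = sample_treatment_days(self.interval, expo, n=125, seed=1)
        merged = days.merge(expo, on=["patient_id", "date"])
        assert ((merged["equivalent_dose"] > 0.0) & (merged["equivalent_dose"] <= 1.5)).all()

    def test_no_qualifying_days_is_an_error(self):
        expo = make_exposures(10, 3.0)
        with pytest.raises(InsufficientDataError):
            sample_treatment_days(self.interval, expo, n=5, seed=0)

    def test_inclusion_frequency_is_uniform_over_seeds(self):
        """Monte-Carlo check: each qualifying day is picked with frequency n/N."""
        n_days, n, reps = 200, 50, 400
        expo = make_exposures(n_days, 1.0)
        hits = np.zeros(n_days)
        for seed in range(reps):
            picked = sample_treatment_days(self.interval, expo, n=n, seed=seed)
            hits[[expo["date"].tolist().index(d) for d in picked["date"]]] += 1
        # chi-square goodness of fit against uniform expectation
        expected = reps * n / n_days
        chi2 = float(((hits - expected) ** 2 / expected).sum())
        p = stats.chi2.sf(chi2, df=n_days - 1)
        assert p > 1e-3


class TestAECounting:
    def test_dictionary_token_examples(self):
        d = frozenset({"tremor", "sedation"})
        assert count_ae_mentions("pt reports tremor and sedation", d) == 2
        assert count_ae_mentions("pt calm and settled tonight", d) == 0
        assert count_ae_mentions("Tremor TREMOR tremor.", d) == 2  # punctuation blocks exact match

    def test_empty_dictionary_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            count_ae_mentions("anything", frozenset())

    def test_packaged_dictionary_loads_nonempty_single_tokens(self, ae_dictionary):
        assert len(ae_dictionary) >= 50
        assert all(" " not in term for term in ae_dictionary)

    def test_matches_generator_ground_truth_counts(self, small_cohort, ae_dictionary):
        sample = small_cohort.notes.head(300)
        truth = small_cohort.note_ae_counts[:300]
        found = np.array([count_ae_mentions(t, ae_dictionary) for t in sample["text"]])
        assert (found == truth).all()


class TestEstimateRate:
    interval = AEInterval(method="ddd", label="low", lower=0.0, upper=1.5,
                          bin_indices=(1, 2, 3))

    def _frames(self):
        days = pd.DataFrame(
            {"patient_id": ["p1", "p1"], "date": pd.to_datetime(["2005-01-01", "2005-01-02"])}
        )
        notes = make_notes(
            [
                ("p1", "2005-01-01", "physician", "tremor " + " ".join(["calm"] * 499)),
                ("p1", "2005-01-02", "nursing", " ".join(["settled"] * 490) + " tremor" * 10),
                ("p1", "2005-03-01", "nursing", "tremor tremor tremor"),  # not sampled
            ]
        )
        return days, notes

    def test_pooled_rate_is_total_ae_over_total_words(self):
        days, notes = self._frames()
        est = estimate_rate(self.interval, days, notes, frozenset({"tremor"}))
        assert est.ae_count == 11
        assert est.word_count == 1000
        assert est.rate == pytest.approx(0.011)

    def test_zero_ae_gives_zero_rate(self):
        days, notes = self._frames()
        est = estimate_rate(self.interval, days, notes, frozenset({"akathisia"}))
        assert est.rate == 0.0

    def test_pooling_is_invariant_to_day_grouping(self):
        days, notes = self._frames()
        d = frozenset({"tremor"})
        whole = estimate_rate(self.interval, days, notes, d)
        parts = [
            estimate_rate(self.interval, days.iloc[[i]], notes, d) for i in range(2)
        ]
        assert whole.ae_count == sum(p.ae_count for p in parts)
        assert whole.word_count == sum(p.word_count for p in parts)
        assert whole.rate == pytest.approx(
            sum(p.ae_count for p in parts) / sum(p.word_count for p in parts)
        )

    def test_zero_words_is_undefined_rate(self):
        days = pd.DataFrame(
            {"patient_id": ["p9"], "date": pd.to_datetime(["2005-01-01"])}
        )
        notes = make_notes([("p1", "2005-01-01", "physician", "hello")])
        with pytest.raises(UndefinedRateError):
            estimate_rate(self.interval, days, notes, frozenset({"tremor"}))


class TestFlatnessRecovery:
    def test_constant_generator_rate_gives_mutually_consistent_intervals(self, tmp_path):
        """With a constant per-word AE probability, the low/mid/high interval
        estimates should be statistically indistinguishable (pairwise
        two-proportion tests at alpha=0.01) in at least 19 of 20 seeded runs."""
        from itertools import combinations

        from statsmodels.stats.proportion import proportions_ztest

        from dosewords import GeneratorConfig, generate_cohort, run_pipeline
        from dosewords.io import PipelineConfig

        consistent = 0
        for seed in range(20):
            cohort = generate_cohort(GeneratorConfig(n_patients=120, seed=300 + seed))
            cfg = PipelineConfig(
                patients="-", prescriptions="-", notes="-",
                out_dir=tmp_path / f"run{seed}",
                methods=("ddd",), subsets=("all",),
                min_patients_note_length=10, seed=300 + seed,
            )
            with np.errstate(all="ignore"):
                res = run_pipeline(
                    cfg, frames=(cohort.patients, cohort.prescriptions, cohort.notes)
                )
            rates = res["ae_rates"]
            assert len(rates) == 3
            flat = True
            for i, j in combinations(range(3), 2):
                _, p = proportions_ztest(
                    count=[rates["ae_count"].iloc[i], rates["ae_count"].iloc[j]],
                    nobs=[rates["word_count"].iloc[i], rates["word_count"].iloc[j]],
                )
                if p < 0.01:
                    flat = False
            consistent += flat
        assert consistent >= 19
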