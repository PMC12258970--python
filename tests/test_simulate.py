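"""Synthetic-cohort generator: determinism, conservation, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sigkit.analysis import cosine_similarity, rank_correlation
from sigkit.simulate import (
    CohortScenario,
    calibrate_indel_slope,
    generate_reference_signatures,
    mmr_like_signature,
    simulate_cohort,
    simulate_indel_burden,
    simulate_timing,
    spike_hypermutators,
)


class TestReferenceSignatures:
    def test_simplex_and_separation(self):
        sigs = generate_reference_signatures(4, max_pairwise_cosine=0.5, seed=3)
        arr = sigs.values()
        assert arr.shape == (96, 4)
        assert (arr >= 0).all()
        assert np.allclose(arr.sum(axis=0), 1.0, atol=1e-9)
        for i in range(4):
            for j in range(i + 1, 4):
                assert cosine_similarity(arr[:, i], arr[:, j]) < 0.5

    def test_deterministic(self):
        a = generate_reference_signatures(3, seed=42)
        b = generate_reference_signatures(3, seed=42)
        assert (a.values() == b.values()).all()

    def test_infeasible_constraint_errors(self):
        with pytest.raises(RuntimeError, match="cosine"):
            generate_reference_signatures(
                50, max_pairwise_cosine=0.05, seed=1, max_attempts=200
            )

    def test_mmr_like_avoids_baseline(self, four_signatures):
        mmr = mmr_like_signature(four_signatures, seed=9)
        for name in four_signatures.names:
            assert cosine_similarity(mmr.values()[:, 0], four_signatures[name]) < 0.5


class TestSimulateCohort:
    def test_single_signature_sanity(self):
        sigs = generate_reference_signatures(1, seed=5)
        sc = CohortScenario(
            n_samples=10,
            signatures=sigs,
            prevalence=(1.0,),
            contribution_range=((1.0, 1.0),),
            burden_log10_mean=np.log10(5000),
            burden_log10_sd=0.0,
            target_signature_index=0,
            seed=1,
        )
        cohort = simulate_cohort(sc, make_records=False)
        totals = cohort.catalog.column_sums()
        assert (totals == 5000).all()
        aggregate = cohort.catalog.counts.sum(axis=1).to_numpy()
        assert cosine_similarity(aggregate, sigs.values()[:, 0]) >= 0.999

    def test_mixture_matches_truth_aggregate(self):
        """With ~10^6 total mutations the pooled catalog matches the
        exposure-weighted truth mixture (law of large numbers)."""
        sc = CohortScenario(
            n_samples=200,
            burden_log10_mean=np.log10(5000),
            burden_log10_sd=0.0,
            seed=7,
        )
        cohort = simulate_cohort(sc, make_records=False)
        truth_mix = (
            cohort.signatures.values()
            @ cohort.true_exposures.to_numpy()[:4]
        ).sum(axis=1)
        aggregate = cohort.catalog.counts.sum(axis=1).to_numpy()
        assert cosine_similarity(aggregate, truth_mix) >= 0.99

    def test_zero_prevalence_gives_zero_exposure_row(self):
        sc = CohortScenario(
            n_samples=30, prevalence=(1.0, 1.0, 1.0, 0.0), seed=3
        )
        cohort = simulate_cohort(sc, make_records=False)
        assert (cohort.true_exposures.loc[cohort.target_name] == 0).all()

    def test_truth_conservation_and_records(self):
        sc = CohortScenario(
            n_samples=8, burden_log10_mean=2.5, burden_log10_sd=0.2, seed=13
        )
        cohort = simulate_cohort(sc, make_records=True)
        cohort.validate()  # exposures == column sums == record counts

    def test_deterministic_given_seed(self):
        sc = CohortScenario(n_samples=12, burden_log10_mean=3.0, seed=21)
        a = simulate_cohort(sc, make_records=True)
        b = simulate_cohort(sc, make_records=True)
        pd.testing.assert_frame_equal(a.catalog.counts, b.catalog.counts)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_burden_scaling_law(self, four_signatures):
        """Raising burden_log10_mean by log10(2) doubles the median burden.

        Both cohorts share one signature set so the seeded draws align."""
        medians = []
        for mu in (3.5, 3.5 + np.log10(2)):
            sc = CohortScenario(
                n_samples=600, signatures=four_signatures,
                burden_log10_mean=mu, burden_log10_sd=0.3, seed=4,
            )
            cohort = simulate_cohort(sc, make_records=False)
            medians.append(float(cohort.catalog.column_sums().median()))
        assert medians[1] / medians[0] == pytest.approx(2.0, rel=0.10)

    def test_simulated_records_classify_consistently(self):
        """Rebuilding the catalog from the synthesized records through the
        real classification path reproduces the drawn channel counts."""
        from sigkit.catalogs import build_matrix
        from sigkit.timing import _frame_to_records

        sc = CohortScenario(n_samples=5, burden_log10_mean=2.5, seed=2)
        cohort = simulate_cohort(sc, make_records=True)
        recs = _frame_to_records(cohort.records)
        rebuilt = build_matrix(recs, "SBS96", sample_ids=cohort.sample_ids)
        pd.testing.assert_frame_equal(rebuilt.counts, cohort.catalog.counts)


class TestSpikeHypermutators:
    def test_identity_when_zero(self, small_cohort):
        assert spike_hypermutators(small_cohort, n=0) is small_cohort

    def test_exact_burden_and_ratio(self):
        sc = CohortScenario(
            n_samples=40, burden_log10_mean=4.0, burden_log10_sd=0.2, seed=6
        )
        cohort = simulate_cohort(sc, make_records=False)
        spiked = spike_hypermutators(cohort, n=30, burden=100_000)
        totals = spiked.catalog.column_sums()
        hyper = totals[[s for s in totals.index if s.startswith("H")]]
        assert (hyper == 100_000).all()
        baseline = totals[[s for s in totals.index if s.startswith("S")]]
        # repair-deficient burdens run an order of magnitude above baseline
        ratio = hyper.median() / baseline.median()
        assert 5 <= ratio <= 20
        spiked.validate()


class TestTiming:
    def _timed(self, late_fraction=0.9, gained=0.5, enrichment=None, seed=17):
        sc = CohortScenario(
            n_samples=20,
            burden_log10_mean=3.0,
            burden_log10_sd=0.0,
            target_late_fraction=late_fraction,
            seed=seed,
        )
        cohort = simulate_cohort(sc, make_records=True)
        return simulate_timing(cohort, gained, early_enrichment=enrichment)

    def test_symmetric_when_no_bias(self):
        timed = self._timed(late_fraction=0.5)
        rec = timed.records
        nontarget = rec[rec.true_signature != timed.target_name]
        clonal = nontarget[nontarget.timing_truth != "subclonal"]
        frac_early = (clonal.timing_truth == "early").mean()
        assert frac_early == pytest.approx(0.5, abs=0.02)

    def test_target_late_multiplicity(self):
        timed = self._timed(late_fraction=0.9)
        rec = timed.records
        tgt = rec[(rec.true_signature == timed.target_name) & (rec.major_cn >= 2)]
        assert len(tgt) > 100
        assert (tgt.multiplicity == 1).mean() >= 0.80

    def test_no_gain_means_nothing_classifiable(self):
        from sigkit.timing import classify_timing_frame

        timed = self._timed(gained=0.0)
        labels = classify_timing_frame(timed.records)
        assert (labels == "unclassified").all()


class TestIndelBurden:
    def test_null_slope_uncorrelated(self):
        sc = CohortScenario(n_samples=200, burden_log10_mean=3.5, seed=8)
        cohort = simulate_cohort(sc, make_records=False)
        counts = simulate_indel_burden(cohort, slope=0.0)
        frac = cohort.true_exposures.loc[cohort.target_name] / cohort.true_exposures.sum()
        rho = rank_correlation(frac.to_numpy(), counts.to_numpy())
        assert abs(rho) < 0.15

    def test_calibrated_fold_change(self):
        sc = CohortScenario(n_samples=800, burden_log10_mean=4.0, seed=9)
        cohort = simulate_cohort(sc, make_records=False)
        counts = simulate_indel_burden(cohort)  # slope calibrated for 1.3x
        pos = (cohort.true_exposures.loc[cohort.target_name] > 0).to_numpy()
        fold = counts[pos].mean() / counts[~pos].mean()
        assert fold == pytest.approx(1.3, abs=0.1)

    def test_spearman_near_calibrated_value(self):
        """The default noise level was calibrated so the exposure-indel
        Spearman correlation sits near the 0.66 regime; check over seeds."""
        rhos = []
        for seed in range(20):
            sc = CohortScenario(n_samples=300, burden_log10_mean=4.0, seed=100 + seed)
            cohort = simulate_cohort(sc, make_records=False)
            counts = simulate_indel_burden(cohort)
            frac = (
                cohort.true_exposures.loc[cohort.target_name]
                / cohort.true_exposures.sum()
            )
            rhos.append(rank_correlation(frac.to_numpy(), counts.to_numpy()))
        assert np.mean(rhos) == pytest.approx(0.66, abs=0.1)

    def test_hypermutators_get_msi_like_indels(self):
        sc = CohortScenario(n_samples=30, burden_log10_mean=4.0, seed=10)
        cohort = simulate_cohort(sc, make_records=False)
        spiked = spike_hypermutators(cohort, n=5, burden=100_000)
        counts = simulate_indel_burden(spiked)
        hyper = counts[[s for s in counts.index if s.startswith("H")]]
        base = counts[[s for s in counts.index if s.startswith("S")]]
        assert (hyper > 7_000).all()
        assert (base < 7_000).all()
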