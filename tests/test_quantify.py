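"""Assay statistics: frequency, classification, coincidence, D, LOD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from porepulse.pulse_detection import PulseRecord, PulseTable
from porepulse.quantify import (
    ClassThresholds,
    DoseResponse,
    aggregation_degree,
    classify_pulses,
    coincidence_fraction,
    estimate_concentration,
    filter_coincidences,
    fit_frequency_calibration,
    lod_from_dose_response,
    mixture_error,
    pulse_frequency,
)


def make_table(ip_values, td_values=None, duration_s=600.0):
    ip = list(ip_values)
    td = list(td_values) if td_values is not None else [1.0] * len(ip)
    records = [
        PulseRecord(event_id=i, t_start_s=i * 1e-3, ip_na=a, td_ms=d, baseline_na=182.0)
        for i, (a, d) in enumerate(zip(ip, td))
    ]
    return PulseTable(records=records, duration_s=duration_s, metadata={})


class TestPulseFrequency:
    def test_count_over_duration(self):
        assert pulse_frequency(make_table([1.0] * 120, duration_s=600.0)) == 12.0

    def test_empty_table(self):
        assert pulse_frequency(make_table([], duration_s=600.0)) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            PulseTable(records=[], duration_s=0.0)


class TestFrequencyCalibration:
    def test_single_pair_slope(self):
        alpha = fit_frequency_calibration([(2.3e8, 49.1)])
        assert alpha == pytest.approx(2.135e-7, rel=1e-3)

    def test_exact_proportional_data_zero_residual(self):
        conc = np.array([1e8, 5e8, 2e9])
        alpha = fit_frequency_calibration(list(zip(conc, 2.15e-7 * conc)))
        assert alpha == pytest.approx(2.15e-7, rel=1e-12)

    def test_concentration_inversion(self):
        alpha = fit_frequency_calibration([(2.3e8, 49.1)])
        assert estimate_concentration(45.2, alpha) == pytest.approx(2.12e8, rel=5e-3)

    def test_all_zero_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_frequency_calibration([(0.0, 1.0), (0.0, 2.0)])


class TestClassifyPulses:
    def test_simple_split_at_three_na(self):
        est = classify_pulses(make_table([1.5, 2.0, 4.0, 4.5]), ClassThresholds((3.0,)))
        assert est.fractions[1] == pytest.approx(0.5)
        assert est.counts.sum() == est.total == 4

    def test_boundary_goes_to_upper_class(self):
        est = classify_pulses(make_table([1.5, 4.0, 6.0]), ClassThresholds((3.0, 5.9)))
        assert list(est.counts) == [1, 1, 1]
        est2 = classify_pulses(make_table([3.0]), ClassThresholds((3.0,)))
        assert list(est2.counts) == [0, 1]

    def test_binomial_recovery_within_three_sigma(self, rng):
        n, frac = 1000, 0.10
        ip = np.where(rng.random(n) < frac, 4.0, 1.5)
        est = classify_pulses(make_table(ip), ClassThresholds((3.0,)))
        assert abs(est.fractions[1] - frac) <= 3.3 * np.sqrt(frac * (1 - frac) / n)
        assert est.ci_low[1] < est.fractions[1] < est.ci_high[1]

    def test_empty_table_flagged(self):
        est = classify_pulses(make_table([]), ClassThresholds((3.0,)))
        assert est.total == 0
        assert np.isnan(est.fractions).all()

    @given(
        ip=st.lists(st.floats(0.1, 12.0), min_size=1, max_size=50),
        cuts=st.lists(st.floats(0.5, 11.0), min_size=1, max_size=3, unique=True),
    )
    def test_fractions_sum_to_one_counts_conserved(self, ip, cuts):
        est = classify_pulses(make_table(ip), ClassThresholds(tuple(sorted(cuts))))
        assert est.counts.sum() == len(ip)
        assert est.fractions.sum() == pytest.approx(1.0)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassThresholds((5.9, 3.0))
        with pytest.raises(ValueError):
            ClassThresholds((3.0,), ("only-one",))


class TestMixtureError:
    def test_printed_three_bead_worked_example(self):
        err = mixture_error((54.7, 28.9, 16.4), (50.0, 33.3, 16.7))
        assert err.max_pp == pytest.approx(4.7, abs=1e-9)

    def test_identical_vectors(self):
        err = mixture_error((50.0, 50.0), (50.0, 50.0))
        assert err.max_pp == 0.0 and err.mean_pp == 0.0

    def test_hand_computed_example(self):
        err = mixture_error((52.0, 31.3, 16.7), (50.0, 33.3, 16.7))
        np.testing.assert_allclose(err.per_class_pp, [2.0, 2.0, 0.0], atol=1e-9)
        assert err.mean_pp == pytest.approx(4.0 / 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mixture_error((1.0, 2.0), (1.0,))

    @given(
        vecs=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100), st.floats(0, 100)),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_property(self, vecs):
        a, b, c = vecs
        ac = mixture_error(a, c).per_class_pp
        ab = mixture_error(a, b).per_class_pp
        bc = mixture_error(b, c).per_class_pp
        assert np.all(ac <= ab + bc + 1e-9)


class TestCoincidence:
    def test_one_in_four(self):
        table = make_table([1.5, 2.0, 7.0, 2.5])
        assert coincidence_fraction(table, 6.0, 5.0) == 0.25

    def test_none_beyond_cuts(self):
        assert coincidence_fraction(make_table([1.5, 2.0]), 6.0, 5.0) == 0.0

    def test_duration_cut_counts_too(self):
        table = make_table([1.5, 2.0], td_values=[1.0, 6.0])
        assert coincidence_fraction(table, 6.0, 5.0) == 0.5

    def test_filter_removes_candidates(self):
        table = make_table([1.5, 7.0, 2.0], td_values=[1.0, 1.0, 6.0])
        kept = filter_coincidences(table, 6.0, 5.0)
        assert len(kept) == 1 and kept.records[0].ip_na == 1.5

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            coincidence_fraction(make_table([]), 6.0, 5.0)


class TestAggregationDegree:
    def test_pure_monomer_is_one(self):
        assert aggregation_degree(make_table([1.5] * 10), 1.5) == pytest.approx(1.0)

    def test_half_dimers_worked_example(self):
        table = make_table([1.5] * 5 + [2.8] * 5)
        assert aggregation_degree(table, 1.5) == pytest.approx(1.43333, rel=1e-4)

    def test_invariant_to_order_and_duplication(self, rng):
        ip = rng.uniform(1.0, 8.0, 50)
        d1 = aggregation_degree(make_table(ip), 1.5)
        d2 = aggregation_degree(make_table(ip[::-1]), 1.5)
        d3 = aggregation_degree(make_table(np.concatenate([ip, ip])), 1.5)
        assert d1 == pytest.approx(d2) == pytest.approx(d3)

    def test_strictly_increasing_in_any_amplitude(self):
        ip = [1.5, 2.0, 3.0]
        base = aggregation_degree(make_table(ip), 1.5)
        bumped = aggregation_degree(make_table([1.5, 2.5, 3.0]), 1.5)
        assert bumped > base

    def test_errors(self):
        with pytest.raises(ValueError):
            aggregation_degree(make_table([]), 1.5)
        with pytest.raises(ValueError):
            aggregation_degree(make_table([1.5]), 0.0)


def make_dose_response(blank_ds, positive):
    """positive: list of (conc, [D replicates]); frequency filled with 1s."""
    concs = [0.0] + [c for c, _ in positive]
    ds = [list(blank_ds)] + [list(d) for _, d in positive]
    freqs = [[1.0] * len(d) for d in ds]
    return DoseResponse(concentrations_molar=concs, frequencies_per_min=freqs, d_values=ds)


class TestLOD:
    def test_zero_sd_blank_threshold(self):
        dr = make_dose_response([2.64, 2.64, 2.64], [(1e-15, [2.65, 2.66])])
        res = lod_from_dose_response(dr)
        assert res.threshold_d == pytest.approx(2.64)
        assert res.lod_molar == 1e-15

    def test_printed_blank_statistics_threshold(self):
        # blank mean 2.64, SD 6.62e-2 -> threshold 2.8386
        blanks = [2.64 - 6.62e-2, 2.64, 2.64 + 6.62e-2]
        sd = float(np.std(blanks, ddof=1))
        dr = make_dose_response(blanks, [(1e-15, [5.0, 5.0])])
        res = lod_from_dose_response(dr)
        assert res.blank_mean == pytest.approx(2.64)
        assert res.threshold_d == pytest.approx(2.64 + 3 * sd)
        manual = 2.64 + 3 * 6.62e-2
        assert manual == pytest.approx(2.8386)

    def test_monotone_exceedance_from_third_concentration(self):
        dr = make_dose_response(
            [1.0, 1.0, 1.0],
            [(1e-15, [1.0]), (1e-14, [0.9]), (1e-13, [1.5]), (1e-12, [2.0])],
        )
        res = lod_from_dose_response(dr)
        assert res.lod_molar == 1e-13

    def test_single_point_excursion_does_not_qualify(self):
        dr = make_dose_response(
            [1.0, 1.0], [(1e-15, [2.0]), (1e-14, [0.9]), (1e-13, [2.0])]
        )
        assert lod_from_dose_response(dr).lod_molar == 1e-13

    def test_not_detected(self):
        dr = make_dose_response([1.0, 1.0], [(1e-15, [0.9]), (1e-14, [0.95])])
        assert lod_from_dose_response(dr).lod_molar is None

    def test_raising_blanks_never_lowers_lod(self):
        positive = [(1e-15, [1.1]), (1e-14, [1.3]), (1e-13, [2.0])]
        lod_low = lod_from_dose_response(make_dose_response([1.0, 1.0, 1.0], positive))
        lod_high = lod_from_dose_response(
            make_dose_response([1.2, 1.2, 1.2], positive)
        )
        order = [1e-15, 1e-14, 1e-13, np.inf]
        assert order.index(lod_high.lod_molar or np.inf) >= order.index(
            lod_low.lod_molar or np.inf
        )

    def test_fewer_than_two_blanks_rejected(self):
        with pytest.raises(ValueError):
            lod_from_dose_response(make_dose_response([1.0], [(1e-15, [2.0])]))

    def test_missing_blank_rejected(self):
        dr = DoseResponse(
            concentrations_molar=[1e-15],
            frequencies_per_min=[[1.0]],
            d_values=[[2.0]],
        )
        with pytest.raises(ValueError):
            lod_from_dose_response(dr)
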