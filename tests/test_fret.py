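"""Burst calling, intensity corrections, FRET efficiency, sizing, global fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stapull import (
    CorrectionConstants,
    PhotonTrace,
    analyze_trace,
    approximate_size,
    classify_size,
    correct_intensities,
    find_coincident_bins,
    fret_efficiency,
    fret_histogram,
    global_two_gaussian_fit,
    monomer_brightness,
)
from stapull.simulate import TraceSpec, simulate_photon_trace


class TestCoincidentBins:
    def test_threshold_boundary_is_inclusive(self):
        trace = PhotonTrace([8, 7, 0], [8, 100, 0])
        assert list(find_coincident_bins(trace)) == [0]

    def test_all_zero_trace(self):
        trace = PhotonTrace(np.zeros(100, int), np.zeros(100, int))
        assert len(find_coincident_bins(trace)) == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            PhotonTrace([1, 2], [1, 2, 3])


class TestCorrections:
    def test_hand_arithmetic(self):
        k = CorrectionConstants(A_D=2.0, A_A=1.0, C=0.05)
        I_D, I_A = correct_intensities(100.0, 50.0, k)
        assert I_D == pytest.approx(98.0)
        assert I_A == pytest.approx(44.0)

    def test_zero_constants_identity(self):
        I_D, I_A = correct_intensities(37.0, 21.0, CorrectionConstants())
        assert (I_D, I_A) == (37.0, 21.0)

    def test_autofluorescence_cancels_exactly(self):
        I_D, _ = correct_intensities(2.0, 0.0, CorrectionConstants(A_D=2.0))
        assert I_D == 0.0

    def test_efficiency_cases(self):
        assert fret_efficiency(10.0, 10.0) == pytest.approx(0.5)
        assert fret_efficiency(98.0, 44.0) == pytest.approx(44 / 142)
        assert fret_efficiency(5.0, 0.0) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 0.0)


class TestSizing:
    def test_monomer_brightness_is_mean_of_donor_only_bursts(self):
        donor = np.array([20, 30, 40, 100, 0])
        acceptor = np.array([0, 1, 2, 50, 0])  # last donor burst is coincident
        trace = PhotonTrace(donor, acceptor)
        assert monomer_brightness(trace, CorrectionConstants()) == pytest.approx(30.0)

    def test_single_burst(self):
        trace = PhotonTrace([25], [0])
        assert monomer_brightness(trace, CorrectionConstants()) == 25.0

    def test_no_donor_bursts_rejected(self):
        trace = PhotonTrace([1, 2], [0, 0])
        with pytest.raises(ValueError):
            monomer_brightness(trace, CorrectionConstants())

    def test_monomer_trace_recovers_per_unit_brightness(self):
        spec = TraceSpec(
            duration_s=2.0,
            burst_rate_per_s=20.0,
            size_units=1,
            true_E=0.0,
            photons_per_unit=25.0,
            seed=8,
        )
        trace, _ = simulate_photon_trace(spec)
        beta = monomer_brightness(trace, CorrectionConstants())
        assert beta == pytest.approx(25.0, rel=0.1)

    def test_size_formula(self):
        assert approximate_size(6.0, 4.0, 10.0) == pytest.approx(2.0)
        assert approximate_size(100.0, 50.0, 10.0) == pytest.approx(30.0)

    def test_simulated_10mer_size_in_expectation(self):
        sizes = []
        for seed in range(20):
            spec = TraceSpec(
                duration_s=1.0,
                burst_rate_per_s=30.0,
                size_units=10,
                true_E=0.5,
                photons_per_unit=20.0,
                seed=seed,
            )
            trace, _ = simulate_photon_trace(spec)
            bins = find_coincident_bins(trace)
            I_D, I_A = correct_intensities(
                trace.donor_counts[bins], trace.acceptor_counts[bins], CorrectionConstants()
            )
            # half the photons land in each channel: I_monomer = photons/unit
            sizes.extend(approximate_size(I_D, I_A, 2 * 20.0))
        assert np.mean(sizes) == pytest.approx(10.0, rel=0.05)

    def test_size_classes_at_stated_boundaries(self):
        assert classify_size(4.2) == "small"
        assert classify_size(5.0) == "medium"
        assert classify_size(30.0) == "medium"
        assert classify_size(150.0) == "medium"
        assert classify_size(200.0) == "large"

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
    def test_size_classes_partition_positive_axis(self, size):
        assert classify_size(size) in {"small", "medium", "large"}

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            classify_size(-1.0)


class TestAnalyzeTrace:
    def test_burst_table_columns_and_flags(self):
        spec = TraceSpec(
            duration_s=1.0,
            burst_rate_per_s=30.0,
            size_units=20,
            true_E=0.4,
            photons_per_unit=20.0,
            autofluorescence_donor=1.0,
            autofluorescence_acceptor=0.5,
            crosstalk=0.05,
            seed=13,
        )
        trace, truth = simulate_photon_trace(spec)
        k = CorrectionConstants(A_D=1.0, A_A=0.5, C=0.05)
        bursts = analyze_trace(trace, k, I_monomer=40.0)
        assert {"bin", "D", "A", "I_D", "I_A", "E", "size", "size_class", "flag_E"} <= set(
            bursts.columns
        )
        assert len(bursts) > 0
        in_range = bursts[~bursts.flag_E]
        assert ((in_range.E >= 0) & (in_range.E <= 1)).all()
        # most called bursts are true bursts
        assert np.isin(bursts.bin, truth.bin).mean() > 0.9

    def test_round_trip_csv(self, tmp_path):
        trace = PhotonTrace([1, 2, 3], [4, 5, 6])
        trace.to_csv(tmp_path / "t.csv")
        back = PhotonTrace.from_csv(tmp_path / "t.csv")
        np.testing.assert_array_equal(back.donor_counts, [1, 2, 3])
        np.testing.assert_array_equal(back.acceptor_counts, [4, 5, 6])


class TestGlobalFit:
    @staticmethod
    def _mixture_hist(rng, n, w_low, c=(0.3, 0.7), s=0.05):
        n_low = rng.binomial(n, w_low)
        e = np.concatenate(
            [rng.normal(c[0], s, n_low), rng.normal(c[1], s, n - n_low)]
        )
        return fret_histogram(e)

    def test_single_gaussian_gives_negligible_second_component(self):
        rng = np.random.default_rng(21)
        hist = fret_histogram(rng.normal(0.4, 0.05, 10_000))
        fit = global_two_gaussian_fit([hist])
        w = fit.weights[0]
        assert max(w) > 0.95  # one dominant component

    def test_shared_centers_and_per_dataset_weights_recovered(self):
        rng = np.random.default_rng(22)
        hists = [
            self._mixture_hist(rng, 10_000, 0.3),
            self._mixture_hist(rng, 10_000, 0.6),
        ]
        fit = global_two_gaussian_fit(hists)
        assert abs(fit.center_a - 0.3) < 0.02
        assert abs(fit.center_b - 0.7) < 0.02
        assert abs(fit.weights[0][0] - 0.3) < 0.05
        assert abs(fit.weights[1][0] - 0.6) < 0.05

    def test_global_fit_of_single_dataset_matches_independent_fit(self):
        rng = np.random.default_rng(23)
        h1 = self._mixture_hist(rng, 5000, 0.4)
        h2 = self._mixture_hist(rng, 5000, 0.4)
        joint = global_two_gaussian_fit([h1, h2])
        solo = global_two_gaussian_fit([h1])
        # with a single dataset the shared-parameter model reduces exactly to
        # an independent two-Gaussian fit; its centers agree with the joint
        # fit of two same-weight draws
        assert abs(solo.center_a - joint.center_a) < 0.02
        assert abs(solo.center_b - joint.center_b) < 0.02

    def test_degenerate_inputs_rejected(self):
        empty = (np.linspace(0.025, 0.975, 20), np.zeros(20))
        with pytest.raises(ValueError):
            global_two_gaussian_fit([empty])
        with pytest.raises(ValueError):
            global_two_gaussian_fit([])
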