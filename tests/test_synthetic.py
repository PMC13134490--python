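"""Synthetic FSC curves, resolution series, micrographs, alignment tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voltactf import (
    AlignmentTableSpec,
    ImagingCondition,
    PhasePlateModel,
    PhantomSpec,
    SyntheticFscModel,
    fit_rosenthal_henderson,
    fsc_from_model,
    generate_alignment_table,
    generate_resolution_series,
    resolution_at_threshold,
    simulate_micrograph,
)
from voltactf.synthetic import fsc_crossing_closed_form


K_GRID = tuple(np.linspace(0.001, 0.6, 400))


class TestFscFromModel:
    def test_bounded_and_decreasing(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.0)
        curve = fsc_from_model(model, 300702, K_GRID)
        fsc = np.asarray(curve.correlations)
        assert np.all((fsc >= 0) & (fsc < 1))
        assert np.all(np.diff(fsc) < 0)

    def test_flat_when_b_is_zero(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=0.0)
        curve = fsc_from_model(model, 1000, K_GRID)
        assert np.ptp(curve.correlations) == 0.0

    def test_increasing_in_particle_count_and_saturating(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.0)
        lo = np.asarray(fsc_from_model(model, 1000, K_GRID).correlations)
        hi = np.asarray(fsc_from_model(model, 100000, K_GRID).correlations)
        assert np.all(hi > lo)
        huge = np.asarray(fsc_from_model(model, 10**15, (0.01, 0.1)).correlations)
        np.testing.assert_allclose(huge, 1.0, atol=1e-4)

    def test_threshold_crossing_matches_closed_form(self):
        """Numerical crossing of the sampled curve agrees with the analytic
        inversion of S/(S+1) = t."""
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.8, threshold=0.143)
        n = 300702
        k_star = fsc_crossing_closed_form(model, n)
        curve = fsc_from_model(model, n, K_GRID)
        res = resolution_at_threshold(curve, threshold=0.143)
        assert res.k_cross_A_inv == pytest.approx(k_star, rel=1e-3)
        assert res.resolution_A == pytest.approx(1.0 / k_star, rel=1e-3)

    def test_crossing_undefined_for_tiny_n(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.0)
        with pytest.raises(ValueError):
            fsc_crossing_closed_form(model, 100)


class TestGenerateResolutionSeries:
    @pytest.mark.parametrize("b_true", [67.6, 100.8])
    def test_noiseless_fit_recovers_table_b_factors(self, b_true):
        """Generator + fitter are a closed loop: the fit returns the B the
        series was generated with, at both measured apoferritin values."""
        model = SyntheticFscModel(alpha=1e-4, b_A2=b_true)
        series = generate_resolution_series(model, n_total=300702)
        fit = fit_rosenthal_henderson(series)
        assert fit.b_A2 == pytest.approx(b_true, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    @given(b=st.floats(min_value=20.0, max_value=400.0))
    @settings(max_examples=30, deadline=None)
    def test_noiseless_recovery_across_b_range(self, b):
        model = SyntheticFscModel(alpha=1e-4, b_A2=b)
        series = generate_resolution_series(model, n_total=300702)
        assert fit_rosenthal_henderson(series).b_A2 == pytest.approx(b, rel=1e-6)

    def test_ten_percent_subset_counts(self):
        series = generate_resolution_series(
            SyntheticFscModel(alpha=1e-4, b_A2=100.0), n_total=300702
        )
        assert len(series) == 10
        assert series.n_particles[0] == round(0.1 * 300702)
        assert series.n_particles[-1] == 300702

    def test_seed_determinism(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.0)
        a = generate_resolution_series(model, 300702, noise_sd_log=0.03, seed=5)
        b = generate_resolution_series(model, 300702, noise_sd_log=0.03, seed=5)
        c = generate_resolution_series(model, 300702, noise_sd_log=0.03, seed=6)
        assert a.resolution_A == b.resolution_A
        assert a.resolution_A != c.resolution_A

    def test_stochastic_recovery_within_ten_percent(self):
        """Median fitted B over 100 noisy replicates (3% log-normal noise on
        resolutions) stays within 10% of truth for both measured values."""
        for b_true in (67.6, 100.8):
            model = SyntheticFscModel(alpha=1e-4, b_A2=b_true)
            fits = [
                fit_rosenthal_henderson(
                    generate_resolution_series(
                        model, 300702, noise_sd_log=0.03, seed=seed
                    )
                ).b_A2
                for seed in range(100)
            ]
            assert abs(np.median(fits) - b_true) / b_true < 0.10

    def test_invalid_fraction_rejected(self):
        model = SyntheticFscModel(alpha=1e-4, b_A2=100.0)
        with pytest.raises(ValueError):
            generate_resolution_series(model, 300702, fractions=[0.0, 0.5])


class TestSimulateMicrograph:
    SPEC = dict(
        image_side=64,
        pixel_size_A=1.51,
        blobs=(((32.0, 32.0), 15.0, 1.0), ((16.0, 48.0), 8.0, 0.5)),
    )

    def test_zero_dose_gives_all_zero_images(self, vpp_condition):
        spec = PhantomSpec(**self.SPEC, dose_e_per_A2=0.0, seed=1)
        noisy, clean = simulate_micrograph(spec, vpp_condition)
        assert np.all(noisy == 0.0) and np.all(clean == 0.0)

    def test_zero_transfer_gives_zero_signal(self, vpp_condition):
        spec = PhantomSpec(**self.SPEC, dose_e_per_A2=10.0, seed=1)
        _, clean = simulate_micrograph(
            spec, vpp_condition, transfer=np.zeros((64, 64))
        )
        np.testing.assert_allclose(clean, 0.0, atol=1e-12)

    def test_unit_transfer_round_trips_phase_map(self, vpp_condition):
        """With an all-pass filter the noise-free image is the dose-scaled
        phantom itself (forward/inverse transform identity)."""
        spec = PhantomSpec(**self.SPEC, dose_e_per_A2=1.0, seed=1)
        from voltactf.synthetic import _render_phase_map

        _, clean = simulate_micrograph(
            spec, vpp_condition, transfer=np.ones((64, 64))
        )
        np.testing.assert_allclose(clean, _render_phase_map(spec), atol=1e-10)

    def test_seed_determinism(self, vpp_condition):
        spec = PhantomSpec(**self.SPEC, dose_e_per_A2=20.0, seed=3)
        a, _ = simulate_micrograph(spec, vpp_condition)
        b, _ = simulate_micrograph(spec, vpp_condition)
        np.testing.assert_array_equal(a, b)

    def test_low_band_power_favors_vpp_over_high_defocus(self):
        """Parseval check: the |CTF|^2-weighted phantom spectrum summed over
        the alignment band is larger under the median VPP condition than
        under conventional ~2 um defocus imaging."""
        from voltactf.band import FrequencyBand
        from voltactf.optics import FrequencyGrid, ctf_field
        from voltactf.synthetic import _render_phase_map

        spec = PhantomSpec(
            image_side=256,
            pixel_size_A=1.51,
            blobs=(((128.0, 128.0), 60.0, 1.0), ((60.0, 180.0), 30.0, 0.5)),
            dose_e_per_A2=30.0,
            seed=2,
        )
        grid = FrequencyGrid(256, 1.51)
        band = FrequencyBand("R1", 0.002, 0.03)
        mask = band.mask(grid.magnitudes)
        phantom_spectrum = np.abs(np.fft.fft2(_render_phase_map(spec))) ** 2

        def band_power(cond):
            _, clean = simulate_micrograph(spec, cond)
            return float(np.sum(np.abs(np.fft.fft2(clean))[mask] ** 2))

        def parseval_oracle(cond):
            ctf2 = np.abs(ctf_field(grid, cond)) ** 2
            return float(
                spec.dose_e_per_A2**2 * np.sum((phantom_spectrum * ctf2)[mask])
            )

        vpp = ImagingCondition(
            defocus_A=7800.0,
            phase_plate=PhasePlateModel(phase_shift_deg=72.0),
            attenuation_enabled=True,
        )
        plain = ImagingCondition(defocus_A=19700.0, phase_plate=None)
        assert band_power(vpp) == pytest.approx(parseval_oracle(vpp), rel=1e-9)
        assert band_power(plain) == pytest.approx(parseval_oracle(plain), rel=1e-9)
        assert band_power(vpp) > band_power(plain)

    def test_oversized_blob_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(image_side=16, pixel_size_A=1.0, blobs=(((8, 8), 100.0, 1),))


class TestGenerateAlignmentTable:
    def test_zero_sd_pins_axis_to_calibrated(self):
        spec = AlignmentTableSpec(n_tomograms=20, axis_error_sd_deg=0.0, seed=1)
        records = generate_alignment_table(spec)
        assert all(r.tilt_axis_deg == spec.calibrated_axis_deg for r in records)

    def test_zero_flag_probability_gives_no_flags(self):
        spec = AlignmentTableSpec(n_tomograms=50, problematic_patch_prob=0.0, seed=2)
        records = generate_alignment_table(spec)
        assert all(r.flagged_patches == 0 for r in records)

    def test_seed_determinism(self):
        spec = AlignmentTableSpec(n_tomograms=30, seed=9)
        a = generate_alignment_table(spec)
        b = generate_alignment_table(spec)
        assert a == b
        c = generate_alignment_table(AlignmentTableSpec(n_tomograms=30, seed=10))
        assert a != c

    def test_records_respect_invariants(self):
        records = generate_alignment_table(AlignmentTableSpec(n_tomograms=200, seed=4))
        for r in records:
            assert 0 <= r.flagged_patches <= r.total_patches
            assert r.thickness_A > 0
            assert 40.0 <= r.zero_tilt_dose <= 70.0

    def test_axis_sd_recovered_within_sampling_bounds(self):
        """At n = 110 tomograms and sd 9.18 deg, the sample sd lies within
        25% of truth in >= 95% of 200 seeds (chi-square concentration)."""
        from voltactf import summarize_alignment

        hits = 0
        for seed in range(200):
            spec = AlignmentTableSpec(
                n_tomograms=110, axis_error_sd_deg=9.18, seed=seed
            )
            summary = summarize_alignment(
                generate_alignment_table(spec), spec.calibrated_axis_deg
            )
            if abs(summary.axis_sd_deg - 9.18) / 9.18 < 0.25:
                hits += 1
        assert hits >= 190
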