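"""Tests for spectral conditioning: SNV, baseline offset, despiking, pairing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfuse.exceptions import DegenerateSpectrumError, InvalidInputError, PairingError
from specfuse.preprocessing import (
    PreprocessingParams,
    baseline_offset,
    despike,
    pair_and_index,
    preprocess_spectrum,
    snv_region,
)
from specfuse.spectra import FTIR, RAMAN
from specfuse.synthesis import generate_spectrum, inject_cosmic_spikes

from conftest import make_spectrum


class TestSNV:
    def test_three_point_example(self):
        spec = make_spectrum([1.0, 2.0, 3.0])
        out = snv_region(spec)
        np.testing.assert_allclose(out.intensities, [-1.0, 0.0, 1.0])

    def test_region_statistics_after_transform(self, ftir_template):
        spec = generate_spectrum(ftir_template, 1.0, seed=1)
        out = snv_region(spec, (850.0, 2000.0))
        mask = (out.axis >= 850) & (out.axis <= 2000)
        assert out.intensities[mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert out.intensities[mask].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_idempotent_on_normalised_input(self):
        spec = make_spectrum(np.sin(np.linspace(0, 5, 40)))
        once = snv_region(spec)
        twice = snv_region(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            snv_region(make_spectrum(np.ones(20)))

    def test_empty_region_rejected(self):
        spec = make_spectrum(np.arange(20.0))
        with pytest.raises(InvalidInputError):
            snv_region(spec, (10000.0, 11000.0))

    @given(
        gain=st.floats(0.05, 20.0),
        offset=st.floats(-5.0, 5.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_equivariance(self, gain, offset, seed):
        """snv(a*x + b) == snv(x) for a > 0: scatter removed exactly."""
        rng = np.random.default_rng(seed)
        spec = make_spectrum(rng.normal(size=60))
        scaled = spec.with_intensities(gain * spec.intensities + offset)
        np.testing.assert_allclose(
            snv_region(scaled).intensities,
            snv_region(spec).intensities,
            atol=1e-9,
        )


class TestBaselineOffset:
    def test_subtracts_anchor_value(self):
        values = np.linspace(0.2, 1.2, 100)
        spec = make_spectrum(values, axis=700 + 4.0 * np.arange(100))
        anchor = float(spec.axis[30])
        out = baseline_offset(spec, anchor)
        np.testing.assert_allclose(out.intensities, values - values[30])
        assert out.intensities[30] == 0.0

    def test_zero_at_anchor_is_identity(self):
        values = np.sin(np.linspace(0, 3, 50))
        spec = make_spectrum(values - values[20], axis=700 + 4.0 * np.arange(50))
        out = baseline_offset(spec, float(spec.axis[20]))
        np.testing.assert_allclose(out.intensities, spec.intensities)

    def test_nearest_grid_point_matches_explicit_search(self):
        axis = np.array([700.0, 704.0, 708.0, 712.0, 716.0])
        spec = make_spectrum([1.0, 2.0, 3.0, 4.0, 5.0], axis=axis)
        anchor = 709.5
        idx = min(range(len(axis)), key=lambda i: (abs(axis[i] - anchor), axis[i]))
        out = baseline_offset(spec, anchor)
        np.testing.assert_allclose(out.intensities, spec.intensities - spec.intensities[idx])

    def test_exact_tie_breaks_to_lower_wavenumber(self):
        axis = np.array([700.0, 704.0, 708.0])
        spec = make_spectrum([1.0, 5.0, 9.0], axis=axis)
        out = baseline_offset(spec, 702.0)  # tie between 700 and 704
        np.testing.assert_allclose(out.intensities, spec.intensities - 1.0)

    def test_anchor_outside_axis_rejected(self):
        spec = make_spectrum(np.arange(10.0))
        with pytest.raises(InvalidInputError):
            baseline_offset(spec, 5.0)


class TestDespike:
    def test_smooth_noisy_spectrum_unchanged(self):
        rng = np.random.default_rng(0)
        axis = np.arange(400.0, 1400.0, 2.0)
        smooth = 1.0 + 0.5 * np.sin(axis / 120.0) + rng.normal(0, 0.01, axis.size)
        spec = make_spectrum(smooth, modality=RAMAN, axis=axis)
        out = despike(spec)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_single_spike_removed_near_truth(self, raman_template):
        clean = generate_spectrum(raman_template, 1.0, seed=21)
        spiked = inject_cosmic_spikes(clean, rate=1.0, magnitude=8.0, seed=4)
        assert not np.array_equal(spiked.intensities, clean.intensities)
        out = despike(spiked)
        assert np.max(np.abs(out.intensities - clean.intensities)) < 5 * raman_template.noise_sd

    def test_flat_spectrum_spike_only_channels_altered(self, flat_raman):
        x = flat_raman.intensities.copy()
        x[100] += 50.0
        spiked = flat_raman.with_intensities(x)
        out = despike(spiked)
        changed = np.where(out.intensities != spiked.intensities)[0]
        np.testing.assert_array_equal(changed, [100])
        assert out.intensities[100] == pytest.approx(2.5)

    @pytest.mark.parametrize("position", ["first", "last"])
    def test_boundary_spike_removed(self, flat_raman, position):
        idx = 0 if position == "first" else len(flat_raman) - 1
        x = flat_raman.intensities.copy()
        x[idx] += 50.0
        out = despike(flat_raman.with_intensities(x))
        assert out.intensities[idx] == pytest.approx(2.5)

    def test_even_or_tiny_window_rejected(self, flat_raman):
        with pytest.raises(InvalidInputError):
            despike(flat_raman, window=4)
        with pytest.raises(InvalidInputError):
            despike(flat_raman, window=1)


class TestPairing:
    def test_matched_lists_pair_up(self, small_dataset):
        ftir = [s.ftir for s in small_dataset]
        raman = [s.raman for s in small_dataset]
        paired = pair_and_index(ftir, raman)
        assert len(paired) == len(small_dataset)
        assert sorted(paired.sample_ids) == sorted(small_dataset.sample_ids)

    def test_order_independence(self, small_dataset):
        rng = np.random.default_rng(1)
        ftir = [s.ftir for s in small_dataset]
        raman = [s.raman for s in small_dataset]
        shuffled = pair_and_index(
            [ftir[i] for i in rng.permutation(len(ftir))],
            [raman[i] for i in rng.permutation(len(raman))],
        )
        reference = pair_and_index(ftir, raman)
        assert shuffled.sample_ids == reference.sample_ids
        for a, b in zip(shuffled, reference):
            np.testing.assert_array_equal(a.ftir.intensities, b.ftir.intensities)

    def test_missing_partner_names_offender(self, small_dataset):
        ftir = [s.ftir for s in small_dataset]
        raman = [s.raman for s in small_dataset][:-1]
        with pytest.raises(PairingError, match=small_dataset.sample_ids[-1]):
            pair_and_index(ftir, raman)


class TestChain:
    def test_chain_idempotent_at_zero_noise(self, ftir_template):
        from dataclasses import replace

        quiet = replace(ftir_template, noise_sd=0.0, scatter_sd=0.0)
        spec = generate_spectrum(quiet, 1.5, seed=0)
        params = PreprocessingParams()
        once = preprocess_spectrum(spec, params)
        twice = preprocess_spectrum(once, params)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-9)

    def test_scatter_removed_exactly_at_zero_noise(self, ftir_template):
        """Gain/offset scatter has no effect on the SNV output at zero noise."""
        from dataclasses import replace

        quiet = replace(ftir_template, noise_sd=0.0, scatter_sd=0.0)
        noisy_scatter = replace(ftir_template, noise_sd=0.0, scatter_sd=0.3)
        params = PreprocessingParams()
        a = preprocess_spectrum(generate_spectrum(quiet, 2.0, seed=5), params)
        b = preprocess_spectrum(generate_spectrum(noisy_scatter, 2.0, seed=5), params)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9)
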