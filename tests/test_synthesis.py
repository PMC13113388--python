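"""Tests for the paired-spectrum generator."""

import numpy as np
import pytest

from specfuse.exceptions import InvalidInputError
from specfuse.spectra import FTIR, PURE_L, PURE_S, RAMAN, read_dataset, write_dataset
from specfuse.synthesis import (
    DEFAULT_RATIO_PANEL,
    component_fractions,
    generate_paired_dataset,
    generate_spectrum,
    inject_cosmic_spikes,
)


class TestComponentFractions:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (1.0, (0.5, 0.5)),
            (3.0, (0.75, 0.25)),
            (0.25, (0.2, 0.8)),
            (PURE_L, (1.0, 0.0)),
            (PURE_S, (0.0, 1.0)),
        ],
    )
    def test_known_values(self, ratio, expected):
        np.testing.assert_allclose(component_fractions(ratio), expected)

    def test_fractions_sum_to_one(self):
        for r in np.linspace(0.05, 10, 37):
            f_l, f_s = component_fractions(r)
            assert f_l + f_s == pytest.approx(1.0)
            assert 0 < f_l < 1 and 0 < f_s < 1

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf, "pureX"])
    def test_invalid_ratio_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            component_fractions(bad)


class TestGenerateSpectrum:
    def test_same_seed_bitwise_identical(self, ftir_template):
        a = generate_spectrum(ftir_template, 1.5, seed=11)
        b = generate_spectrum(ftir_template, 1.5, seed=11)
        assert np.array_equal(a.intensities, b.intensities)

    def test_different_seeds_differ(self, ftir_template):
        a = generate_spectrum(ftir_template, 1.5, seed=11)
        b = generate_spectrum(ftir_template, 1.5, seed=12)
        assert not np.array_equal(a.intensities, b.intensities)

    def test_pure_s_contains_no_lecithin_signal(self, raman_template):
        from dataclasses import replace

        quiet = replace(raman_template, noise_sd=0.0, scatter_sd=0.0)
        spec = generate_spectrum(quiet, PURE_S, seed=0)
        expected = quiet.lipid_s_signal() + quiet.artifact_signal()
        np.testing.assert_allclose(spec.intensities, expected, atol=1e-12)

    def test_noiseless_mixture_is_template_combination(self, ftir_template):
        from dataclasses import replace

        quiet = replace(ftir_template, noise_sd=0.0, scatter_sd=0.0)
        r = 2.0
        spec = generate_spectrum(quiet, r, seed=0)
        f_l, f_s = r / (1 + r), 1 / (1 + r)
        expected = (
            f_l * quiet.lipid_l_signal()
            + f_s * quiet.lipid_s_signal()
            + quiet.artifact_signal()
        )
        np.testing.assert_allclose(spec.intensities, expected, atol=1e-12)

    def test_signal_affine_in_fractions(self, raman_template):
        """Midpoint in fraction space = elementwise mean of endpoint spectra."""
        from dataclasses import replace

        quiet = replace(raman_template, noise_sd=0.0, scatter_sd=0.0)
        r1, r2 = 0.5, 3.0
        f_mid = 0.5 * (r1 / (1 + r1) + r2 / (1 + r2))
        r_mid = f_mid / (1 - f_mid)
        s1 = generate_spectrum(quiet, r1, seed=0).intensities
        s2 = generate_spectrum(quiet, r2, seed=0).intensities
        s_mid = generate_spectrum(quiet, r_mid, seed=0).intensities
        np.testing.assert_allclose(s_mid, 0.5 * (s1 + s2), atol=1e-10)

    def test_ftir_negative_in_water_stretch_region(self, ftir_template):
        spec = generate_spectrum(ftir_template, 1.0, seed=3)
        region = (spec.axis >= 3200) & (spec.axis <= 3600)
        assert spec.intensities[region].min() < 0

    def test_raman_nonnegative_in_water_stretch_region(self, raman_template):
        spec = generate_spectrum(raman_template, 1.0, seed=3)
        region = (spec.axis >= 3000) & (spec.axis <= 3200)
        assert spec.intensities[region].min() > -5 * raman_template.noise_sd


class TestTemplates:
    def test_ftir_has_negative_water_artifacts(self, ftir_template):
        def has_negative_in(lo, hi):
            return any(
                lo <= p.center <= hi and p.amplitude < 0
                for p in ftir_template.artifact_peaks
            )

        assert has_negative_in(3200, 3600)
        assert has_negative_in(1600, 1700)

    def test_raman_has_silicon_substrate_band(self, raman_template):
        assert any(
            920 <= p.center <= 1000 and p.amplitude > 0
            for p in raman_template.artifact_peaks
        )

    def test_phosphate_bands_only_in_ftir(self, ftir_template, raman_template):
        def phosphate(peaks):
            return [p for p in peaks if "phosphate" in p.label]

        assert len(phosphate(ftir_template.lipid_l_peaks)) >= 1
        assert len(phosphate(ftir_template.lipid_s_peaks)) >= 1
        assert not phosphate(raman_template.lipid_l_peaks)
        assert not phosphate(raman_template.lipid_s_peaks)
        # no Raman lipid band sits on the FTIR phosphate centres
        phos_centers = [
            p.center
            for p in phosphate(ftir_template.lipid_l_peaks + ftir_template.lipid_s_peaks)
        ]
        for peaks in (raman_template.lipid_l_peaks, raman_template.lipid_s_peaks):
            for p in peaks:
                assert all(abs(p.center - c) > 20 for c in phos_centers)


class TestCosmicSpikes:
    def test_zero_rate_is_identity(self, raman_template):
        spec = generate_spectrum(raman_template, 1.0, seed=5)
        out = inject_cosmic_spikes(spec, rate=0.0, magnitude=8.0, seed=1)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_seeded_positions_reproducible(self, raman_template):
        spec = generate_spectrum(raman_template, 1.0, seed=5)
        a = inject_cosmic_spikes(spec, 2.0, 8.0, seed=9)
        b = inject_cosmic_spikes(spec, 2.0, 8.0, seed=9)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_large_spikes_exceed_all_clean_channels(self, raman_template):
        spec = generate_spectrum(raman_template, 1.0, seed=5)
        magnitude = 50.0 * spec.intensities.max()
        out = inject_cosmic_spikes(spec, 3.0, magnitude, seed=2)
        changed = out.intensities != spec.intensities
        assert changed.any()
        assert out.intensities[changed].min() > spec.intensities.max()

    def test_ftir_rejected(self, ftir_template):
        spec = generate_spectrum(ftir_template, 1.0, seed=5)
        with pytest.raises(InvalidInputError):
            inject_cosmic_spikes(spec, 1.0, 8.0, seed=0)


class TestPairedDataset:
    def test_counts(self):
        ds = generate_paired_dataset(ratios=DEFAULT_RATIO_PANEL, replicates=3, seed=0)
        assert len(ds) == 39
        assert len({s.sample_id for s in ds}) == 39

    def test_default_panel_spans_quarter_steps(self):
        np.testing.assert_allclose(DEFAULT_RATIO_PANEL, np.arange(1, 14) * 0.25)

    def test_pairs_share_label_and_id(self, small_dataset):
        for sample in small_dataset:
            assert sample.ftir.sample_id == sample.raman.sample_id == sample.sample_id
            assert sample.ftir.ls_ratio == sample.raman.ls_ratio == sample.ls_ratio
            assert sample.ftir.modality == FTIR
            assert sample.raman.modality == RAMAN

    def test_seeded_reproducibility(self):
        a = generate_paired_dataset(ratios=(1.0, 2.0), replicates=2, seed=3)
        b = generate_paired_dataset(ratios=(1.0, 2.0), replicates=2, seed=3)
        c = generate_paired_dataset(ratios=(1.0, 2.0), replicates=2, seed=4)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.ftir.intensities, sb.ftir.intensities)
            np.testing.assert_array_equal(sa.raman.intensities, sb.raman.intensities)
        assert not np.array_equal(a[0].ftir.intensities, c[0].ftir.intensities)

    def test_include_pure_adds_marker_samples(self):
        ds = generate_paired_dataset(
            ratios=(1.0,), replicates=1, seed=0, include_pure=True
        )
        labels = set(ds.ls_labels)
        assert PURE_L in labels and PURE_S in labels
        assert len(ds.drop_pure()) == 1

    def test_csv_round_trip(self, tmp_path, small_dataset):
        manifest = write_dataset(small_dataset, tmp_path / "data")
        loaded = read_dataset(manifest)
        assert loaded.sample_ids == small_dataset.sample_ids
        for a, b in zip(loaded, small_dataset):
            assert a.ls_ratio == pytest.approx(b.ls_ratio)
            np.testing.assert_allclose(a.ftir.intensities, b.ftir.intensities)
            np.testing.assert_allclose(a.raman.axis, b.raman.axis)
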