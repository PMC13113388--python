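"""Spectral conditioning: despiking, baseline offset, region-anchored SNV.

The conditioning chain is fixed as despike -> baseline offset -> SNV.
Each step acts on a single spectrum only — no statistic is shared across
spectra, so preprocessing one spectrum can never leak information into
another (which also keeps train/test hygiene trivially intact).

SNV (standard normal variate) here is *region-anchored*: the location and
scale are estimated on a designated spectral interval free of substrate or
environmental character, then applied to every channel.  Defaults follow
the study design: 850–2000 cm^-1 for FTIR (avoiding the CO2 and water
stretch regions), the whole spectrum for Raman.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .exceptions import (
    DegenerateSpectrumError,
    InvalidInputError,
    PairingError,
)
from .spectra import FTIR, RAMAN, PairedDataset, PairedSample, Spectrum

Interval = tuple[float, float]


def snv_region(spectrum: Spectrum, region: Interval | None = None) -> Spectrum:
    """Standard normal variate with parameters estimated on *region*.

    Subtracts the mean and divides by the sample standard deviation (ddof=1)
    of the channels inside the closed interval ``region``; the transform is
    applied to *all* channels.  ``region=None`` uses the full axis.
    """
    x = spectrum.intensities
    if region is None:
        mask = np.ones_like(x, dtype=bool)
    else:
        lo, hi = region
        if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
            raise InvalidInputError(f"invalid SNV region {region!r}")
        mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    if mask.sum() < 3:
        raise InvalidInputError(
            f"SNV region {region!r} covers {int(mask.sum())} channels; need >= 3"
        )
    loc = x[mask].mean()
    scale = x[mask].std(ddof=1)
    if scale <= 0 or not np.isfinite(scale):
        raise DegenerateSpectrumError(
            f"zero variance in SNV region for sample {spectrum.sample_id!r}"
        )
    return spectrum.with_intensities((x - loc) / scale)


def baseline_offset(spectrum: Spectrum, anchor: float = 2500.0) -> Spectrum:
    """Subtract the intensity at the grid point nearest *anchor* (cm^-1).

    Exact distance ties break toward the lower wavenumber, so the result is
    deterministic on any grid.
    """
    axis = spectrum.axis
    if not (axis[0] <= anchor <= axis[-1]):
        raise InvalidInputError(
            f"baseline anchor {anchor} cm^-1 outside axis range "
            f"[{axis[0]}, {axis[-1]}]"
        )
    idx = int(np.argmin(np.abs(axis - anchor)))  # argmin -> first = lower wavenumber
    return spectrum.with_intensities(spectrum.intensities - spectrum.intensities[idx])


def despike(spectrum: Spectrum, window: int = 5, threshold: float = 15.0) -> Spectrum:
    """Remove single-channel cosmic spikes with a running-median / MAD test.

    A channel is flagged when its deviation from the running median (window
    of *window* channels) exceeds ``threshold * 1.4826 * MAD`` of the
    deviations; flagged channels are replaced by linear interpolation from
    the nearest non-flagged channels.  The
    window is mirror-padded at the boundaries (reflection without repeating
    the edge sample): plain edge replication would fill the window with
    copies of a spiked edge channel, making the running median equal the
    spike and letting boundary spikes through.  If the MAD is exactly zero
    (flat or noise-free input) any non-zero deviation is treated as a spike.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidInputError("despike window must be odd and >= 3")
    if threshold <= 0:
        raise InvalidInputError("despike threshold must be positive")
    x = spectrum.intensities
    # Robust per-channel noise floor from the first difference.  The MAD of
    # the median-filter deviations alone underestimates the noise (the
    # centre channel frequently *is* the window median, so the deviation
    # distribution has an atom at zero), which would let band-curvature
    # deviations of genuine peaks cross the threshold.
    diffs = np.diff(x)
    noise_mad = np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0)

    def flags_and_median(reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        running = median_filter(reference, size=window, mode="mirror")
        deviation = x - running
        mad = np.median(np.abs(deviation - np.median(deviation)))
        scale = 1.4826 * max(mad, noise_mad)
        if scale > 0:
            return np.abs(deviation) > threshold * scale, running
        return deviation != 0, running

    # Two detection passes: a spike biases the running median of its
    # *neighbours*, which can falsely flag steep-flank channels next to it;
    # the second pass recomputes the median on the provisionally cleaned
    # signal so only channels deviating from an uncontaminated local median
    # stay flagged.
    flagged, running = flags_and_median(x)
    provisional = np.where(flagged, running, x)
    flagged, _ = flags_and_median(provisional)
    if not flagged.any():
        return spectrum.with_intensities(x.copy())
    if flagged.all():
        return spectrum.with_intensities(provisional)
    # Replace flagged channels by linear interpolation from the nearest
    # non-flagged neighbours: a running median is biased by one-two channels
    # on steep band flanks, interpolation is not.
    cleaned = x.copy()
    good = ~flagged
    cleaned[flagged] = np.interp(
        spectrum.axis[flagged], spectrum.axis[good], x[good]
    )
    return spectrum.with_intensities(cleaned)


def pair_and_index(
    ftir: list[Spectrum], raman: list[Spectrum]
) -> PairedDataset:
    """Match FTIR and Raman spectra by sample id into a paired dataset.

    Requires a one-to-one correspondence of sample ids.  Output order is
    sorted by sample id, so the pairing is independent of input order.
    """
    ftir_by_id = _index_unique(ftir, FTIR)
    raman_by_id = _index_unique(raman, RAMAN)
    missing_raman = sorted(set(ftir_by_id) - set(raman_by_id))
    missing_ftir = sorted(set(raman_by_id) - set(ftir_by_id))
    if missing_raman or missing_ftir:
        parts = []
        if missing_raman:
            parts.append(f"no Raman partner for {missing_raman}")
        if missing_ftir:
            parts.append(f"no FTIR partner for {missing_ftir}")
        raise PairingError("; ".join(parts))
    samples = []
    for sample_id in sorted(ftir_by_id):
        f, r = ftir_by_id[sample_id], raman_by_id[sample_id]
        if f.ls_ratio != r.ls_ratio:
            raise PairingError(
                f"sample {sample_id!r}: L/S labels differ between modalities "
                f"({f.ls_ratio!r} vs {r.ls_ratio!r})"
            )
        samples.append(PairedSample(sample_id, f.ls_ratio, f, r))
    return PairedDataset(samples)


def _index_unique(spectra: list[Spectrum], modality: str) -> dict[str, Spectrum]:
    out: dict[str, Spectrum] = {}
    for spec in spectra:
        if spec.modality != modality:
            raise PairingError(
                f"expected only {modality} spectra, found {spec.modality} "
                f"for sample {spec.sample_id!r}"
            )
        if spec.sample_id in out:
            raise PairingError(f"duplicate sample id {spec.sample_id!r} in {modality} list")
        out[spec.sample_id] = spec
    return out


@dataclass
class PreprocessingParams:
    """Per-modality conditioning parameters (defaults follow the study design)."""

    ftir_snv_region: Interval | None = (850.0, 2000.0)
    raman_snv_region: Interval | None = None  # None = whole spectrum
    baseline_anchor: float = 2500.0
    baseline_modalities: tuple[str, ...] = (FTIR,)
    despike_modalities: tuple[str, ...] = (RAMAN,)
    despike_window: int = 5
    despike_threshold: float = 15.0

    def snv_region_for(self, modality: str) -> Interval | None:
        return self.ftir_snv_region if modality == FTIR else self.raman_snv_region


def preprocess_spectrum(spectrum: Spectrum, params: PreprocessingParams) -> Spectrum:
    """Apply the despike -> baseline offset -> SNV chain to one spectrum."""
    out = spectrum
    if spectrum.modality in params.despike_modalities:
        out = despike(out, params.despike_window, params.despike_threshold)
    if spectrum.modality in params.baseline_modalities:
        out = baseline_offset(out, params.baseline_anchor)
    return snv_region(out, params.snv_region_for(spectrum.modality))


def preprocess_dataset(
    dataset: PairedDataset, params: PreprocessingParams | None = None
) -> PairedDataset:
    """Condition every spectrum of a paired dataset (pairing preserved)."""
    params = params or PreprocessingParams()
    samples = [
        PairedSample(
            sample_id=s.sample_id,
            ls_ratio=s.ls_ratio,
            ftir=preprocess_spectrum(s.ftir, params),
            raman=preprocess_spectrum(s.raman, params),
        )
        for s in dataset
    ]
    return PairedDataset(samples)
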