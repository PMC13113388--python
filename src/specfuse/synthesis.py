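"""Synthetic paired FTIR/Raman spectra of two-lipid vesicle mixtures.

The generator emulates the phenomenology of attenuated-total-reflectance
FTIR and micro-Raman measurements of aqueous DPPC (lecithin, L) /
sphingomyelin (S) vesicles:

* two-component linear mixing of per-lipid peak templates, with mixing
  fractions ``f_L = r/(1+r)``, ``f_S = 1/(1+r)`` for L/S ratio ``r`` at
  constant total lipid;
* ATR-FTIR water artifacts — negative bands near 3200–3600 cm^-1
  (OH stretch), ~1645 cm^-1 (OH bend) and ~800 cm^-1 (librations) left by
  imperfect water background subtraction;
* a strong silicon-substrate 2TO band in the 920–1000 cm^-1 region of the
  Raman spectra, plus a broad fluorescence baseline;
* phosphate-group bands (1000–1300 cm^-1) present in the FTIR lipid
  templates but absent from the Raman ones — the complementarity that
  motivates fusing the two modalities;
* per-spectrum multiplicative gain and additive offset (scatter), additive
  Gaussian noise, and (Raman only) cosmic-ray spikes.

Peak positions and amplitudes are *configuration*, placed at
literature-typical lipid band positions; they are not claimed to be a
physical model of either instrument.  The default noise levels are chosen
so that single-modality PLSR on the default panel reaches test R^2 in the
high-0.8/0.9 regime typical of this kind of measurement, with FTIR the
noisier modality (water obscures much of its mid-IR information).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError
from .spectra import (
    FTIR,
    RAMAN,
    LSLabel,
    PURE_L,
    PURE_S,
    PairedDataset,
    PairedSample,
    Spectrum,
    is_pure_marker,
    validate_ls_label,
)

#: The L/S ratio panel of the study: 0.25 to 3.25 in steps of 0.25.
DEFAULT_RATIO_PANEL: tuple[float, ...] = tuple(
    round(0.25 * k, 2) for k in range(1, 14)
)

_SHAPES = ("gaussian", "lorentzian")
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PeakSpec:
    """One spectral band: centre and FWHM in cm^-1, signed peak amplitude.

    ``label`` names the vibrational assignment (free text); labels containing
    ``"phosphate"`` mark phosphate-group bands, which by construction occur
    only in the FTIR lipid templates.
    """

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.width > 0 and np.isfinite(self.width)):
            raise InvalidInputError(f"peak width must be positive, got {self.width}")
        if self.shape not in _SHAPES:
            raise InvalidInputError(f"peak shape must be one of {_SHAPES}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Evaluate the band on *axis* (peak value = ``amplitude`` at centre)."""
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "gaussian":
            sigma = self.width * _FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        half = self.width / 2.0
        return self.amplitude * half**2 / (x**2 + half**2)


@dataclass
class ModalityTemplate:
    """All ingredients needed to synthesise one modality's spectra.

    ``baseline_coeffs`` are polynomial coefficients (low order first) in the
    normalised axis coordinate u in [0, 1]; for Raman they model the broad
    fluorescence background, for FTIR a small residual instrument baseline.
    """

    modality: str
    axis: np.ndarray
    lipid_l_peaks: list[PeakSpec]
    lipid_s_peaks: list[PeakSpec]
    artifact_peaks: list[PeakSpec]
    baseline_coeffs: Sequence[float] = field(default_factory=lambda: (0.0,))
    noise_sd: float = 0.01
    scatter_sd: float = 0.05

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.axis.ndim != 1 or self.axis.size < 2 or not np.all(np.diff(self.axis) > 0):
            raise InvalidInputError("template axis must be a strictly increasing 1-D grid")
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise InvalidInputError("noise_sd and scatter_sd must be non-negative")
        lo, hi = self.axis[0], self.axis[-1]
        for peak in (*self.lipid_l_peaks, *self.lipid_s_peaks, *self.artifact_peaks):
            if not (lo <= peak.center <= hi):
                raise InvalidInputError(
                    f"peak at {peak.center} cm^-1 outside axis range [{lo}, {hi}]"
                )

    def _sum(self, peaks: Sequence[PeakSpec]) -> np.ndarray:
        total = np.zeros_like(self.axis)
        for peak in peaks:
            total += peak.profile(self.axis)
        return total

    def lipid_l_signal(self) -> np.ndarray:
        return self._sum(self.lipid_l_peaks)

    def lipid_s_signal(self) -> np.ndarray:
        return self._sum(self.lipid_s_peaks)

    def baseline(self) -> np.ndarray:
        u = (self.axis - self.axis[0]) / (self.axis[-1] - self.axis[0])
        return np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coeffs, float))

    def artifact_signal(self) -> np.ndarray:
        """Artifact bands plus the smooth baseline (everything not lipid)."""
        return self._sum(self.artifact_peaks) + self.baseline()


def default_ftir_template(noise_sd: float = 0.011, scatter_sd: float = 0.10) -> ModalityTemplate:
    """ATR-FTIR template: 700–4000 cm^-1 at 4 cm^-1 spacing (826 channels)."""
    axis = np.arange(700.0, 4000.0 + 4.0, 4.0)
    lipid_l = [
        PeakSpec(2956, 22, 0.35, label="CH3 asym stretch"),
        PeakSpec(2918, 30, 1.00, label="CH2 asym stretch"),
        PeakSpec(2850, 25, 0.70, label="CH2 sym stretch"),
        PeakSpec(1738, 25, 0.55, label="ester C=O stretch"),
        PeakSpec(1467, 20, 0.30, label="CH2 scissoring"),
        PeakSpec(1228, 40, 0.45, label="phosphate PO2- asym stretch"),
        PeakSpec(1170, 25, 0.20, label="CO-O-C asym stretch"),
        PeakSpec(1088, 35, 0.50, label="phosphate PO2- sym stretch"),
        PeakSpec(970, 20, 0.25, label="choline N+(CH3)3 stretch"),
    ]
    lipid_s = [
        PeakSpec(3290, 60, 0.20, label="amide A N-H stretch"),
        PeakSpec(2918, 30, 0.85, label="CH2 asym stretch"),
        PeakSpec(2850, 25, 0.60, label="CH2 sym stretch"),
        PeakSpec(1642, 30, 0.40, label="amide I"),
        PeakSpec(1548, 30, 0.25, label="amide II"),
        PeakSpec(1468, 20, 0.25, label="CH2 scissoring"),
        PeakSpec(1228, 40, 0.30, label="phosphate PO2- asym stretch"),
        PeakSpec(1085, 35, 0.35, label="phosphate PO2- sym stretch"),
        PeakSpec(968, 20, 0.28, label="choline N+(CH3)3 stretch"),
    ]
    # Negative residual water bands from imperfect background subtraction.
    artifacts = [
        PeakSpec(3400, 350, -0.80, label="water OH stretch (negative)"),
        PeakSpec(1645, 80, -0.35, label="water OH bend (negative)"),
        PeakSpec(800, 120, -0.25, label="water libration (negative)"),
    ]
    return ModalityTemplate(
        modality=FTIR,
        axis=axis,
        lipid_l_peaks=lipid_l,
        lipid_s_peaks=lipid_s,
        artifact_peaks=artifacts,
        baseline_coeffs=(0.10, 0.05),
        noise_sd=noise_sd,
        scatter_sd=scatter_sd,
    )


def default_raman_template(noise_sd: float = 0.0035, scatter_sd: float = 0.10) -> ModalityTemplate:
    """Micro-Raman template: 400–3200 cm^-1 at 2 cm^-1 spacing (1401 channels)."""
    axis = np.arange(400.0, 3200.0 + 2.0, 2.0)
    lipid_l = [
        PeakSpec(2882, 30, 0.90, label="CH2 asym stretch"),
        PeakSpec(2847, 25, 1.00, label="CH2 sym stretch"),
        PeakSpec(1440, 25, 0.55, label="CH2 scissoring"),
        PeakSpec(1296, 20, 0.40, label="CH2 twisting"),
        PeakSpec(1128, 18, 0.30, label="C-C trans stretch"),
        PeakSpec(1064, 18, 0.32, label="C-C trans stretch"),
        PeakSpec(718, 15, 0.25, label="choline C-N stretch"),
    ]
    lipid_s = [
        PeakSpec(2930, 30, 0.35, label="CH3 sym stretch"),
        PeakSpec(2885, 30, 0.85, label="CH2 asym stretch"),
        PeakSpec(2850, 25, 0.80, label="CH2 sym stretch"),
        PeakSpec(1670, 22, 0.30, label="sphingosine C=C stretch"),
        PeakSpec(1440, 25, 0.50, label="CH2 scissoring"),
        PeakSpec(1296, 20, 0.35, label="CH2 twisting"),
        PeakSpec(1064, 18, 0.25, label="C-C trans stretch"),
        PeakSpec(718, 15, 0.28, label="choline C-N stretch"),
    ]
    artifacts = [
        PeakSpec(950, 40, 1.20, label="Si substrate 2TO band"),
    ]
    return ModalityTemplate(
        modality=RAMAN,
        axis=axis,
        lipid_l_peaks=lipid_l,
        lipid_s_peaks=lipid_s,
        artifact_peaks=artifacts,
        baseline_coeffs=(0.30, 1.00, -0.80),  # broad fluorescence hump
        noise_sd=noise_sd,
        scatter_sd=scatter_sd,
    )


def component_fractions(ls_ratio: LSLabel) -> tuple[float, float]:
    """Map an L/S ratio label to mixing fractions ``(f_L, f_S)``.

    ``f_L = r/(1+r)`` and ``f_S = 1/(1+r)``, so the two fractions always sum
    to one (constant total lipid).  The pure-endpoint markers map to (1, 0)
    and (0, 1).
    """
    if is_pure_marker(ls_ratio):
        return (1.0, 0.0) if ls_ratio == PURE_L else (0.0, 1.0)
    r = float(validate_ls_label(ls_ratio))
    return r / (1.0 + r), 1.0 / (1.0 + r)


def generate_spectrum(
    template: ModalityTemplate,
    ls_ratio: LSLabel,
    seed,
    sample_id: str = "sample",
) -> Spectrum:
    """Synthesise one spectrum from a template at a given L/S ratio.

    intensities = gain * (f_L*L + f_S*S + artifacts + baseline) + offset + noise
    with gain ~ 1 + N(0, scatter_sd), offset ~ N(0, scatter_sd) and i.i.d.
    channel noise ~ N(0, noise_sd).  Identical (template, ls_ratio, seed)
    give bitwise-identical output.
    """
    f_l, f_s = component_fractions(ls_ratio)
    rng = np.random.default_rng(seed)
    clean = (
        f_l * template.lipid_l_signal()
        + f_s * template.lipid_s_signal()
        + template.artifact_signal()
    )
    gain = 1.0 + rng.normal(0.0, template.scatter_sd)
    offset = rng.normal(0.0, template.scatter_sd)
    noise = rng.normal(0.0, template.noise_sd, size=template.axis.size)
    return Spectrum(
        axis=template.axis.copy(),
        intensities=gain * clean + offset + noise,
        modality=template.modality,
        sample_id=sample_id,
        ls_ratio=ls_ratio,
    )


def inject_cosmic_spikes(
    spectrum: Spectrum, rate: float, magnitude: float, seed
) -> Spectrum:
    """Add Poisson(rate) single-channel positive cosmic-ray spikes (Raman only).

    Cosmic spikes are a CCD-detector phenomenon, so applying this to an FTIR
    spectrum is an error.
    """
    if spectrum.modality != RAMAN:
        raise InvalidInputError("cosmic spikes apply to Raman spectra only")
    if rate < 0 or not np.isfinite(rate):
        raise InvalidInputError(f"spike rate must be >= 0, got {rate}")
    rng = np.random.default_rng(seed)
    n_spikes = int(rng.poisson(rate))
    intensities = spectrum.intensities.copy()
    if n_spikes:
        positions = rng.integers(0, intensities.size, size=n_spikes)
        np.add.at(intensities, positions, magnitude)
    return spectrum.with_intensities(intensities)


def generate_paired_dataset(
    ratios: Sequence[LSLabel] = DEFAULT_RATIO_PANEL,
    replicates: int = 6,
    seed: int | None = 0,
    ftir_template: ModalityTemplate | None = None,
    raman_template: ModalityTemplate | None = None,
    spike_rate: float = 1.0,
    spike_magnitude: float = 8.0,
    include_pure: bool = False,
) -> PairedDataset:
    """Generate a seeded paired FTIR+Raman dataset over an L/S ratio panel.

    Each (ratio, replicate) combination yields one FTIR and one Raman
    spectrum sharing a sample id and label.  Raman spectra receive cosmic
    spikes at ``spike_rate`` per spectrum.  ``include_pure`` appends the two
    pure-endpoint samples (markers, not numeric ratios).
    """
    if not len(ratios):
        raise InvalidInputError("ratio panel must be non-empty")
    if replicates < 1:
        raise InvalidInputError("replicates must be >= 1")
    ftir_template = ftir_template or default_ftir_template()
    raman_template = raman_template or default_raman_template()
    labels: list[LSLabel] = [validate_ls_label(r) for r in ratios]
    if include_pure:
        labels += [PURE_L, PURE_S]

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    samples: list[PairedSample] = []
    for label in labels:
        tag = label if is_pure_marker(label) else f"LS{float(label):.2f}"
        for rep in range(replicates):
            ss_ftir, ss_raman, ss_spike = root.spawn(3)
            sample_id = f"{tag}_r{rep:02d}"
            ftir = generate_spectrum(ftir_template, label, ss_ftir, sample_id)
            raman = generate_spectrum(raman_template, label, ss_raman, sample_id)
            raman = inject_cosmic_spikes(raman, spike_rate, spike_magnitude, ss_spike)
            samples.append(PairedSample(sample_id, label, ftir, raman))
    return PairedDataset(samples)
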