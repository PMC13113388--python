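"""Data-fusion strategies for the two spectroscopic modalities.

Three ways to combine FTIR and Raman information:

* **low-level** — concatenate the two SNV-normalised spectra of a sample
  into one long vector (FTIR block first) and train a single regression on
  the fused axis of sequential data points;
* **high-level mean** — average the two single-modality model outputs;
* **high-level weighted** — inverse-variance weighting of the two outputs,
  with each modality's variance proxied from its conformal prediction
  interval width, sigma ~= (upper - lower) / (2 z), and weight w = 1/sigma^2.

The weighted combination also pools the uncertainties:
sigma_fused = (1/sigma_F^2 + 1/sigma_R^2)^(-1/2), so the fused interval is
never wider than the narrower of the two inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conformal import PredictionInterval
from .exceptions import DegenerateWeightsError, InvalidInputError, PairingError
from .spectra import FTIR, RAMAN, LSLabel, Spectrum


@dataclass
class FusedSpectrum:
    """Concatenated FTIR+Raman intensity vector on a sequential index axis.

    ``fused_index`` is 0-based bookkeeping, *not* a physical wavenumber
    axis; ``block_boundary`` is the index of the first Raman channel.
    """

    values: np.ndarray
    fused_index: np.ndarray
    block_boundary: int
    sample_id: str
    ls_ratio: LSLabel

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FusionWeights:
    """Inverse-variance weights (units 1/ratio^2); only their ratio matters."""

    w_ftir: float
    w_raman: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.w_ftir) and np.isfinite(self.w_raman)):
            raise InvalidInputError("fusion weights must be finite")
        if self.w_ftir < 0 or self.w_raman < 0:
            raise InvalidInputError("fusion weights must be non-negative")
        if self.w_ftir == 0 and self.w_raman == 0:
            raise DegenerateWeightsError("both fusion weights are zero")

    def normalised(self) -> tuple[float, float]:
        total = self.w_ftir + self.w_raman
        return self.w_ftir / total, self.w_raman / total


def fuse_low_level(ftir: Spectrum, raman: Spectrum) -> FusedSpectrum:
    """Row-wise concatenation of one sample's SNV-processed spectra.

    Order is fixed FTIR-then-Raman.  Both inputs must carry the same sample
    id (the pairing contract).
    """
    if ftir.modality != FTIR or raman.modality != RAMAN:
        raise InvalidInputError("fuse_low_level expects (FTIR, Raman) in that order")
    if ftir.sample_id != raman.sample_id:
        raise PairingError(
            f"cannot fuse different samples: {ftir.sample_id!r} vs {raman.sample_id!r}"
        )
    values = np.concatenate([ftir.intensities, raman.intensities])
    return FusedSpectrum(
        values=values,
        fused_index=np.arange(values.size),
        block_boundary=len(ftir),
        sample_id=ftir.sample_id,
        ls_ratio=ftir.ls_ratio,
    )


def fuse_high_level_mean(pred_ftir: float, pred_raman: float) -> float:
    """High-level (decision-level) fusion as the mean of the two model outputs."""
    return 0.5 * (float(pred_ftir) + float(pred_raman))


def mean_fusion_interval(
    pi_ftir: PredictionInterval, pi_raman: PredictionInterval, z: float = 1.96
) -> PredictionInterval:
    """Interval for the mean-output model: per-sample mean of the two bounds.

    This is the perfectly-correlated combination sigma = (s_F + s_R)/2 — a
    conservative choice, since the two modality models predict the same
    quantity from the same sample and their errors are far from independent.
    """
    return PredictionInterval.from_bounds(
        point=fuse_high_level_mean(pi_ftir.point, pi_raman.point),
        lower=0.5 * (pi_ftir.lower + pi_raman.lower),
        upper=0.5 * (pi_ftir.upper + pi_raman.upper),
        z=z,
    )


def sigma_from_interval(lower: float, upper: float, z: float = 1.96) -> float:
    """Uncertainty proxy from an interval: sigma = (upper - lower) / (2 z)."""
    if z <= 0:
        raise InvalidInputError(f"z must be positive, got {z}")
    if upper < lower:
        raise InvalidInputError(f"invalid interval: upper {upper} < lower {lower}")
    return (float(upper) - float(lower)) / (2.0 * z)


def inverse_variance_weights(sigma_ftir: float, sigma_raman: float) -> FusionWeights:
    """Weights w = 1/sigma^2 per modality.

    A single zero sigma is the limit in which that modality receives all
    weight, returned as (1, 0) / (0, 1) without dividing by zero; both zero
    is degenerate.
    """
    if sigma_ftir < 0 or sigma_raman < 0:
        raise InvalidInputError("sigmas must be non-negative")
    if sigma_ftir == 0 and sigma_raman == 0:
        raise DegenerateWeightsError("both sigmas are zero; weights undefined")
    if sigma_ftir == 0:
        return FusionWeights(1.0, 0.0)
    if sigma_raman == 0:
        return FusionWeights(0.0, 1.0)
    return FusionWeights(1.0 / sigma_ftir**2, 1.0 / sigma_raman**2)


def pooled_sigma(sigma_ftir: float, sigma_raman: float) -> float:
    """Inverse-variance pooled uncertainty (1/s_F^2 + 1/s_R^2)^(-1/2)."""
    if sigma_ftir < 0 or sigma_raman < 0:
        raise InvalidInputError("sigmas must be non-negative")
    if sigma_ftir == 0 or sigma_raman == 0:
        return 0.0
    return 1.0 / np.sqrt(1.0 / sigma_ftir**2 + 1.0 / sigma_raman**2)


def fuse_weighted(
    pred_ftir: float,
    pi_ftir: PredictionInterval,
    pred_raman: float,
    pi_raman: PredictionInterval,
    z: float = 1.96,
) -> PredictionInterval:
    """Per-sample inverse-variance weighted fusion of two model outputs.

    The fused point is (w_F p_F + w_R p_R)/(w_F + w_R) with w = 1/sigma^2
    derived from each interval's width; the fused interval is the symmetric
    point +- z * sigma_fused with the pooled sigma, so its width never
    exceeds the narrower input width.
    """
    s_f = sigma_from_interval(pi_ftir.lower, pi_ftir.upper, z)
    s_r = sigma_from_interval(pi_raman.lower, pi_raman.upper, z)
    weights = inverse_variance_weights(s_f, s_r)
    a_f, a_r = weights.normalised()
    point = a_f * float(pred_ftir) + a_r * float(pred_raman)
    sigma = pooled_sigma(s_f, s_r)
    return PredictionInterval(
        point=point, lower=point - z * sigma, upper=point + z * sigma, sigma=sigma
    )
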