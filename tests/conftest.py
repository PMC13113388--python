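import numpy as np
import pytest

from specfuse.spectra import FTIR, RAMAN, Spectrum
from specfuse.synthesis import (
    default_ftir_template,
    default_raman_template,
    generate_paired_dataset,
)


@pytest.fixture(scope="session")
def ftir_template():
    return default_ftir_template()


@pytest.fixture(scope="session")
def raman_template():
    return default_raman_template()


@pytest.fixture(scope="session")
def small_dataset():
    """A small paired dataset (5 ratios x 2 replicates) for fast unit tests."""
    return generate_paired_dataset(
        ratios=(0.5, 1.0, 1.5, 2.0, 3.0), replicates=2, seed=7
    )


@pytest.fixture
def flat_raman():
    """A flat, noiseless Raman spectrum (despiking edge cases)."""
    axis = np.arange(400.0, 900.0, 2.0)
    return Spectrum(
        axis=axis,
        intensities=np.full(axis.size, 2.5),
        modality=RAMAN,
        sample_id="flat",
        ls_ratio=1.0,
    )


def make_spectrum(intensities, modality=FTIR, axis=None, sample_id="s", ls_ratio=1.0):
    intensities = np.asarray(intensities, dtype=float)
    if axis is None:
        axis = 700.0 + 4.0 * np.arange(intensities.size)
    return Spectrum(
        axis=np.asarray(axis, dtype=float),
        intensities=intensities,
        modality=modality,
        sample_id=sample_id,
        ls_ratio=ls_ratio,
    )
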