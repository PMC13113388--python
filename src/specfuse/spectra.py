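"""Spectrum containers and plain-text I/O.

A :class:`Spectrum` is one modality's intensity trace on a physical axis
(wavenumber for FTIR, Raman shift for Raman, both in cm^-1), tagged with a
sample identity and its lecithin/sphingomyelin (L/S) composition label.
Index-matched FTIR+Raman spectra of the same vesicle sample form a
:class:`PairedSample`; a list of those is a :class:`PairedDataset`, the
pairing contract that every later train/test and cross-validation split
must preserve.

Spectra are stored on disk as two-column CSV (``wavenumber,intensity`` or
``raman_shift,intensity``) together with a manifest CSV mapping sample ids
to file paths and L/S labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, PairingError

FTIR = "FTIR"
RAMAN = "Raman"
MODALITIES = (FTIR, RAMAN)

#: Markers for the pure-endpoint samples (pure lecithin / pure sphingomyelin).
#: They carry no numeric L/S ratio and are excluded from regression by default.
PURE_L = "pure_L"
PURE_S = "pure_S"

#: Type of an L/S label: a positive ratio or a pure-endpoint marker.
LSLabel = Union[float, str]

_AXIS_NAMES = {FTIR: "wavenumber", RAMAN: "raman_shift"}


def is_pure_marker(label: LSLabel) -> bool:
    return isinstance(label, str) and label in (PURE_L, PURE_S)


def validate_ls_label(label: LSLabel) -> LSLabel:
    """Return a validated L/S label (positive finite float or pure marker)."""
    if is_pure_marker(label):
        return label
    try:
        value = float(label)
    except (TypeError, ValueError):
        raise InvalidInputError(f"invalid L/S label: {label!r}")
    if not np.isfinite(value) or value <= 0:
        raise InvalidInputError(
            f"L/S ratio must be positive and finite, got {value!r}"
        )
    return value


@dataclass
class Spectrum:
    """One modality's intensity trace on a strictly increasing cm^-1 axis."""

    axis: np.ndarray
    intensities: np.ndarray
    modality: str
    sample_id: str
    ls_ratio: LSLabel

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.modality not in MODALITIES:
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        if self.axis.ndim != 1 or self.axis.shape != self.intensities.shape:
            raise InvalidInputError("axis and intensities must be equal-length 1-D")
        if self.axis.size < 2 or not np.all(np.diff(self.axis) > 0):
            raise InvalidInputError("axis must be strictly increasing")
        if not (np.all(np.isfinite(self.axis)) and np.all(np.isfinite(self.intensities))):
            raise InvalidInputError("axis and intensities must be finite")
        self.ls_ratio = validate_ls_label(self.ls_ratio)

    def __len__(self) -> int:
        return self.axis.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensity values on the same axis."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {_AXIS_NAMES[self.modality]: self.axis, "intensity": self.intensities}
        )


@dataclass
class PairedSample:
    """Index-matched FTIR + Raman spectra sharing one sample id and L/S label."""

    sample_id: str
    ls_ratio: LSLabel
    ftir: Spectrum
    raman: Spectrum

    def __post_init__(self) -> None:
        for spec, modality in ((self.ftir, FTIR), (self.raman, RAMAN)):
            if spec.modality != modality:
                raise PairingError(
                    f"sample {self.sample_id!r}: expected a {modality} spectrum, "
                    f"got {spec.modality}"
                )
            if spec.sample_id != self.sample_id:
                raise PairingError(
                    f"sample id mismatch: pair {self.sample_id!r} holds spectrum "
                    f"{spec.sample_id!r}"
                )

    def spectrum(self, modality: str) -> Spectrum:
        if modality == FTIR:
            return self.ftir
        if modality == RAMAN:
            return self.raman
        raise InvalidInputError(f"unknown modality {modality!r}")


@dataclass
class PairedDataset:
    """Ordered collection of paired samples with matrix/label accessors."""

    samples: list[PairedSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[PairedSample]:
        return iter(self.samples)

    def __getitem__(self, key):
        if isinstance(key, (list, np.ndarray)):
            return PairedDataset([self.samples[int(i)] for i in key])
        if isinstance(key, slice):
            return PairedDataset(self.samples[key])
        return self.samples[int(key)]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ls_labels(self) -> list[LSLabel]:
        return [s.ls_ratio for s in self.samples]

    def drop_pure(self) -> "PairedDataset":
        """Dataset restricted to samples with numeric L/S ratios."""
        return PairedDataset([s for s in self.samples if not is_pure_marker(s.ls_ratio)])

    def targets(self) -> np.ndarray:
        """Numeric L/S targets; raises if pure-endpoint markers are present."""
        labels = self.ls_labels
        if any(is_pure_marker(v) for v in labels):
            raise InvalidInputError(
                "dataset contains pure-endpoint samples; call drop_pure() or map "
                "them to numeric values before modelling"
            )
        return np.asarray(labels, dtype=float)

    def matrix(self, modality: str) -> np.ndarray:
        """Stack one modality's intensities into an (n_samples, n_channels) array."""
        rows = [s.spectrum(modality).intensities for s in self.samples]
        if not rows:
            raise InvalidInputError("empty dataset")
        return np.vstack(rows)

    def map_pure(self, pure_l_value: float | None, pure_s_value: float | None) -> "PairedDataset":
        """Assign numeric L/S values to pure endpoints (None = drop that endpoint)."""
        out: list[PairedSample] = []
        for s in self.samples:
            if s.ls_ratio == PURE_L:
                if pure_l_value is None:
                    continue
                value = validate_ls_label(pure_l_value)
            elif s.ls_ratio == PURE_S:
                if pure_s_value is None:
                    continue
                value = validate_ls_label(pure_s_value)
            else:
                out.append(s)
                continue
            out.append(
                PairedSample(
                    sample_id=s.sample_id,
                    ls_ratio=value,
                    ftir=replace(s.ftir, ls_ratio=value),
                    raman=replace(s.raman, ls_ratio=value),
                )
            )
        return PairedDataset(out)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column CSV with a modality-appropriate header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spectrum.to_frame().to_csv(path, index=False)
    return path


def read_spectrum_csv(
    path: str | Path, modality: str, sample_id: str, ls_ratio: LSLabel
) -> Spectrum:
    """Read a two-column spectrum CSV written by :func:`write_spectrum_csv`."""
    frame = pd.read_csv(path)
    axis_name = _AXIS_NAMES.get(modality)
    if axis_name is None:
        raise InvalidInputError(f"unknown modality {modality!r}")
    if axis_name not in frame.columns or "intensity" not in frame.columns:
        raise InvalidInputError(
            f"{path}: expected columns {axis_name!r} and 'intensity', "
            f"found {list(frame.columns)}"
        )
    return Spectrum(
        axis=frame[axis_name].to_numpy(),
        intensities=frame["intensity"].to_numpy(),
        modality=modality,
        sample_id=sample_id,
        ls_ratio=ls_ratio,
    )


def _format_label(label: LSLabel) -> str:
    return label if is_pure_marker(label) else repr(float(label))


def _parse_label(raw: str) -> LSLabel:
    text = str(raw).strip()
    if text in (PURE_L, PURE_S):
        return text
    return float(text)


def write_dataset(dataset: PairedDataset, directory: str | Path) -> Path:
    """Write all spectra plus a ``manifest.csv`` into *directory*.

    Manifest columns: sample_id, ls_ratio, ftir_path, raman_path (paths
    relative to the manifest location).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for sample in dataset:
        ftir_rel = f"{sample.sample_id}_ftir.csv"
        raman_rel = f"{sample.sample_id}_raman.csv"
        write_spectrum_csv(sample.ftir, directory / ftir_rel)
        write_spectrum_csv(sample.raman, directory / raman_rel)
        records.append(
            {
                "sample_id": sample.sample_id,
                "ls_ratio": _format_label(sample.ls_ratio),
                "ftir_path": ftir_rel,
                "raman_path": raman_rel,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str | Path) -> PairedDataset:
    """Load a paired dataset from a manifest CSV written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    frame = pd.read_csv(manifest_path, dtype=str)
    required = {"sample_id", "ls_ratio", "ftir_path", "raman_path"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    samples = []
    for row in frame.itertuples(index=False):
        label = _parse_label(row.ls_ratio)
        samples.append(
            PairedSample(
                sample_id=row.sample_id,
                ls_ratio=label,
                ftir=read_spectrum_csv(base / row.ftir_path, FTIR, row.sample_id, label),
                raman=read_spectrum_csv(base / row.raman_path, RAMAN, row.sample_id, label),
            )
        )
    return PairedDataset(samples)
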