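"""Containers and preprocessing for absorbance spectra on a shared wavenumber grid.

A :class:`SpectralDataset` holds an ``(n_spectra, n_points)`` absorbance
matrix together with per-spectrum metadata (sample id, replicate id, class
label) and the :class:`WavenumberGrid` every spectrum lives on.  The default
grid is the mid-infrared serum range 700-4000 cm^-1 at 4 cm^-1 steps
(826 points).

Preprocessing is deliberately minimal: replicate averaging (the pointwise
arithmetic mean over repeat acquisitions of one sample) is the only step
applied by default; min-max and unit-vector normalization are available but
opt-in.  Spectra on a different grid are rejected, never resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AxisMismatchError, DataError, LabelConflictError

logger = logging.getLogger(__name__)

#: Canonical class order used in all reports.
DEFAULT_CLASSES = ("AS", "RA", "OA", "HC")

NORMALIZATION_METHODS = ("none", "minmax", "vector")


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform ascending wavenumber axis in cm^-1."""

    start: float = 700.0
    stop: float = 4000.0
    step: float = 4.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise DataError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise DataError(f"grid step must be positive, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step + 1e-9)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @classmethod
    def from_axis(cls, axis: np.ndarray, rtol: float = 1e-6) -> "WavenumberGrid":
        """Infer a uniform grid from an explicit axis; descending axes are reversed."""
        axis = np.asarray(axis, dtype=float)
        if axis.ndim != 1 or axis.size < 2:
            raise AxisMismatchError("wavenumber axis must be 1-D with >= 2 points")
        if axis[0] > axis[-1]:
            logger.info("descending wavenumber axis reversed to ascending on read")
            axis = axis[::-1]
        steps = np.diff(axis)
        step = steps.mean()
        if step <= 0 or not np.allclose(steps, step, rtol=rtol, atol=abs(step) * rtol):
            raise AxisMismatchError("wavenumber axis is not uniformly spaced")
        return cls(start=float(axis[0]), stop=float(axis[-1]), step=float(step))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return (
            np.isclose(self.start, other.start)
            and np.isclose(self.stop, other.stop)
            and np.isclose(self.step, other.step)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((round(self.start, 6), round(self.stop, 6), round(self.step, 6)))


@dataclass(frozen=True)
class Spectrum:
    """One absorbance spectrum with its identity."""

    sample_id: str
    replicate_id: int
    class_label: str
    absorbance: np.ndarray


@dataclass
class SpectralDataset:
    """Absorbance spectra sharing one wavenumber grid.

    ``absorbance`` has shape ``(n_spectra, grid.n_points)``; ``meta`` has the
    columns ``sample_id``, ``replicate_id``, ``class_label`` aligned with the
    rows of ``absorbance``.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: pd.DataFrame
    class_names: tuple = field(default=DEFAULT_CLASSES)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            self.absorbance = self.absorbance.reshape(len(self.meta), -1)
        self.class_names = tuple(self.class_names)
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_spectra(
        cls, grid: WavenumberGrid, spectra: Sequence[Spectrum], class_names=None
    ) -> "SpectralDataset":
        if class_names is None:
            seen: list[str] = []
            for s in spectra:
                if s.class_label not in seen:
                    seen.append(s.class_label)
            class_names = tuple(seen) if seen else DEFAULT_CLASSES
        absorbance = np.vstack([s.absorbance for s in spectra]) if spectra else np.empty((0, grid.n_points))
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "replicate_id": [int(s.replicate_id) for s in spectra],
                "class_label": [s.class_label for s in spectra],
            }
        )
        return cls(grid=grid, absorbance=absorbance, meta=meta, class_names=class_names)

    # -- protocol ---------------------------------------------------------
    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            row = self.meta.iloc[i]
            yield Spectrum(
                sample_id=str(row["sample_id"]),
                replicate_id=int(row["replicate_id"]),
                class_label=str(row["class_label"]),
                absorbance=self.absorbance[i],
            )

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        n = self.absorbance.shape[0]
        if len(self.meta) != n:
            raise DataError(f"metadata rows ({len(self.meta)}) != spectra ({n})")
        if n and self.absorbance.shape[1] != self.grid.n_points:
            raise AxisMismatchError(
                f"absorbance length {self.absorbance.shape[1]} != grid n_points {self.grid.n_points}"
            )
        if n and not np.all(np.isfinite(self.absorbance)):
            bad = int(np.argwhere(~np.isfinite(self.absorbance))[0][0])
            raise DataError(f"non-finite absorbance in spectrum row {bad}")
        unknown = set(self.meta["class_label"]) - set(self.class_names)
        if unknown:
            raise DataError(f"class labels {sorted(unknown)} not in class_names {self.class_names}")
        dup = self.meta.duplicated(subset=["sample_id", "replicate_id"])
        if dup.any():
            row = self.meta[dup].iloc[0]
            raise DataError(
                f"duplicate (sample_id, replicate_id) = ({row['sample_id']}, {row['replicate_id']})"
            )

    # -- views ------------------------------------------------------------
    def subset(self, row_indices: np.ndarray) -> "SpectralDataset":
        row_indices = np.asarray(row_indices)
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance[row_indices],
            meta=self.meta.iloc[row_indices].reset_index(drop=True),
            class_names=self.class_names,
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "SpectralDataset":
        wanted = set(map(str, sample_ids))
        mask = self.meta["sample_id"].astype(str).isin(wanted).to_numpy()
        return self.subset(np.flatnonzero(mask))

    @property
    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    @property
    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[c] for c in self.meta["class_label"]], dtype=int)

    def class_counts(self) -> dict:
        vc = self.meta["class_label"].value_counts()
        return {c: int(vc.get(c, 0)) for c in self.class_names}


# ---------------------------------------------------------------------------
# operations


def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Collapse repeat acquisitions to one spectrum per sample.

    The pointwise arithmetic mean over a sample's replicates becomes the
    sample's spectrum; the class label is carried through and must agree
    across replicates.  Applying this to an already-averaged dataset is the
    identity (every sample has one replicate).
    """
    rows = []
    means = []
    order = ds.meta["sample_id"].drop_duplicates().tolist()
    grouped = ds.meta.groupby("sample_id", sort=False)
    for sid in order:
        idx = grouped.get_group(sid).index.to_numpy()
        labels = set(ds.meta.loc[idx, "class_label"])
        if len(labels) > 1:
            raise LabelConflictError(
                f"sample {sid!r} has conflicting class labels {sorted(labels)}"
            )
        means.append(ds.absorbance[idx].mean(axis=0))
        rows.append({"sample_id": sid, "replicate_id": 0, "class_label": labels.pop()})
    absorbance = np.vstack(means) if means else np.empty((0, ds.grid.n_points))
    return SpectralDataset(
        grid=ds.grid, absorbance=absorbance, meta=pd.DataFrame(rows,
        columns=["sample_id", "replicate_id", "class_label"]), class_names=ds.class_names
    )


def normalize(ds: SpectralDataset, method: str = "none") -> SpectralDataset:
    """Per-spectrum intensity normalization.

    ``minmax`` maps each spectrum onto [0, 1]; ``vector`` scales to unit
    Euclidean norm; ``none`` is the identity (and the default throughout,
    since the acquisition protocol this mirrors applies no normalization).
    A constant spectrum under ``minmax`` (or an all-zero one under
    ``vector``) becomes all zeros, with a warning logged instead of a
    division blow-up.
    """
    if method not in NORMALIZATION_METHODS:
        raise DataError(f"unknown normalization method {method!r}; choose from {NORMALIZATION_METHODS}")
    if method == "none":
        return ds
    a = ds.absorbance.copy()
    if method == "minmax":
        lo = a.min(axis=1, keepdims=True)
        rng = a.max(axis=1, keepdims=True) - lo
        flat = rng[:, 0] == 0
        rng[flat] = 1.0
        a = (a - lo) / rng
        a[flat] = 0.0
        if flat.any():
            logger.warning("minmax normalization: %d constant spectra set to zero", int(flat.sum()))
    else:  # vector
        norm = np.linalg.norm(a, axis=1, keepdims=True)
        zero = norm[:, 0] == 0
        norm[zero] = 1.0
        a = a / norm
        if zero.any():
            logger.warning("vector normalization: %d zero spectra left as zero", int(zero.sum()))
    return SpectralDataset(grid=ds.grid, absorbance=a, meta=ds.meta.copy(), class_names=ds.class_names)


def mean_spectrum_by_class(ds: SpectralDataset) -> Mapping[str, dict]:
    """Per-class mean spectrum with the pointwise min-max envelope.

    Returns ``{class: {"mean": v, "lower": v, "upper": v}}`` for each class
    present in ``class_names``; a class with no spectra is an error.  This
    backs the mean-spectra-with-shaded-envelope style of figure.
    """
    out: dict[str, dict] = {}
    labels = ds.labels
    for cname in ds.class_names:
        mask = labels == cname
        if not mask.any():
            raise DataError(f"class {cname!r} has no spectra")
        block = ds.absorbance[mask]
        out[cname] = {
            "mean": block.mean(axis=0),
            "lower": block.min(axis=0),
            "upper": block.max(axis=0),
        }
    return out
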