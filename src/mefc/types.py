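"""Shared in-memory containers for the pipeline.

All volumes are (x, y, z) or (x, y, z, t) numpy arrays in RAS+ world
orientation with geometry carried by a NIfTI-style 4x4 affine (mm).
Times are milliseconds throughout (TR, TE), matching scanner convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionSpec",
    "DfEntry",
    "MultiEchoSeries",
    "BoldSeries",
    "Parcellation",
    "default_affine",
    "MB_ACQUISITION",
    "MBME_ACQUISITION",
]


def default_affine(voxel_mm: Sequence[float] = (3.0, 3.0, 3.0)) -> np.ndarray:
    """RAS+ affine with the given voxel edge lengths and origin at voxel 0."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


@dataclass(frozen=True)
class AcquisitionSpec:
    """EPI acquisition timing: TR, echo times, volume count, voxel geometry.

    Parameters
    ----------
    tr_ms : repetition time in milliseconds.
    te_ms : ordered echo times in milliseconds (one entry for single-echo).
    n_volumes : number of volumes acquired.
    voxel_mm : voxel edge lengths in mm.
    duration_s : nominal scan duration in seconds (informational).
    """

    tr_ms: float
    te_ms: tuple[float, ...]
    n_volumes: int
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        te = tuple(float(t) for t in self.te_ms)
        object.__setattr__(self, "te_ms", te)
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if len(te) == 0 or any(t <= 0 for t in te):
            raise ValueError("te_ms must be non-empty and positive")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError(f"te_ms must be strictly increasing, got {te}")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    @classmethod
    def from_duration(
        cls,
        tr_ms: float,
        te_ms: Sequence[float],
        duration_s: float,
        voxel_mm: Sequence[float] = (3.0, 3.0, 3.0),
    ) -> "AcquisitionSpec":
        """Volume count from scan duration, rounded to the nearest volume.

        Rounding (not floor) reproduces both printed counts of the emulated
        study design: 360 s at TR 650 ms -> 554 volumes, 360 s at TR 900 ms
        -> 400 volumes.
        """
        n = int(round(duration_s * 1000.0 / tr_ms))
        return cls(tr_ms=tr_ms, te_ms=tuple(te_ms), n_volumes=n,
                   voxel_mm=tuple(voxel_mm), duration_s=duration_s)


#: The two emulated acquisitions: a multiband single-echo scan and a
#: multiband multi-echo scan, both 6 minutes, 3 mm isotropic.
MB_ACQUISITION = AcquisitionSpec.from_duration(650.0, (30.0,), 360.0)
MBME_ACQUISITION = AcquisitionSpec.from_duration(900.0, (11.0, 30.0, 49.0), 360.0)


@dataclass(frozen=True)
class DfEntry:
    """One degrees-of-freedom ledger record.

    ``counted`` distinguishes regressor removal (counted toward the df loss
    used for inference) from informational entries such as the number of
    frequency bins zeroed by the bandpass filter.
    """

    stage: str
    n_removed: int
    counted: bool = True


@dataclass
class MultiEchoSeries:
    """Per-echo 4D time series sharing one grid, mask, and timing."""

    data: list[np.ndarray]
    te_ms: tuple[float, ...]
    tr_ms: float
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if len(self.data) != len(self.te_ms):
            raise ValueError(
                f"{len(self.data)} echo arrays for {len(self.te_ms)} echo times"
            )
        shapes = {d.shape for d in self.data}
        if len(shapes) != 1:
            raise ValueError(f"echo arrays differ in shape: {sorted(shapes)}")
        shape = self.data[0].shape
        if len(shape) != 4:
            raise ValueError(f"echo arrays must be 4D, got shape {shape}")
        if self.mask.shape != shape[:3]:
            raise ValueError("mask shape does not match echo volumes")
        te = tuple(float(t) for t in self.te_ms)
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("te_ms must be strictly increasing")
        self.te_ms = te
        self.mask = self.mask.astype(bool)

    @property
    def n_echoes(self) -> int:
        return len(self.data)

    @property
    def n_volumes(self) -> int:
        return self.data[0].shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data[0].shape[:3]


@dataclass
class BoldSeries:
    """A single (combined or denoised) 4D BOLD series.

    Carries a degrees-of-freedom ledger so that downstream inference can
    discount nuisance regressors removed during denoising.
    """

    data: np.ndarray
    tr_ms: float
    mask: np.ndarray
    affine: np.ndarray
    df_ledger: list[DfEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data volume")
        self.mask = self.mask.astype(bool)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def total_df_loss(self) -> int:
        """Sum of counted ledger entries (regressors removed)."""
        total = sum(e.n_removed for e in self.df_ledger if e.counted)
        if total >= self.n_volumes:
            raise ValueError(
                f"df loss {total} >= {self.n_volumes} time points"
            )
        return total

    def with_data(self, data: np.ndarray, entry: DfEntry | None = None) -> "BoldSeries":
        """New series sharing geometry, optionally appending a ledger entry."""
        ledger = list(self.df_ledger)
        if entry is not None:
            ledger.append(entry)
        return BoldSeries(data=data, tr_ms=self.tr_ms, mask=self.mask,
                          affine=self.affine, df_ledger=ledger)


ROI_CLASSES = ("cortical", "subcortical", "seed")


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus a label table.

    The table has columns ``label`` (positive int), ``name`` (str) and
    ``class`` (one of cortical / subcortical / seed).
    """

    labels: np.ndarray
    table: pd.DataFrame
    affine: np.ndarray

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        required = {"label", "name", "class"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        if self.table["label"].duplicated().any():
            dupes = self.table.loc[self.table["label"].duplicated(), "label"]
            raise ValueError(f"duplicate labels in table: {sorted(set(dupes))}")
        bad = set(self.table["class"]) - set(ROI_CLASSES)
        if bad:
            raise ValueError(f"unknown ROI classes {sorted(bad)}")
        in_volume = set(np.unique(self.labels)) - {0}
        missing = in_volume - set(self.table["label"])
        if missing:
            raise ValueError(f"labels present in volume but not table: {sorted(missing)}")

    def labels_of_class(self, classes: Sequence[str]) -> list[int]:
        """Labels of the requested classes, subcortical block first, then
        cortical, then seed, each in ascending label order."""
        out: list[int] = []
        for cls in ("subcortical", "cortical", "seed"):
            if cls in classes:
                sub = self.table.loc[self.table["class"] == cls, "label"]
                out.extend(sorted(int(v) for v in sub))
        return out

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label
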