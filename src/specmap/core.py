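"""Core containers for spectral maps and QC bookkeeping.

The central object is :class:`SpectralMap`: a dense ``n_pixels x
n_wavenumbers`` absorbance matrix tied to a strictly ascending wavenumber
axis (cm^-1), optional acquisition-grid metadata, and one sample identifier
per pixel row.  All pipeline stages consume and return ``SpectralMap``
instances; per-pixel exclusions are tracked separately in :class:`QCMask`
so that excluded positions can be repopulated for spatial mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import MaskError, ParameterError, ShapeError

__all__ = [
    "GridSpec",
    "SpectralMap",
    "QCMask",
    "PCAResult",
    "ClusterAssignment",
    "REASON_EMPTY",
    "REASON_SCATTER",
    "REASON_MANUAL",
]

REASON_EMPTY = "empty"
REASON_SCATTER = "scatter"
REASON_MANUAL = "manual"
_VALID_REASONS = (REASON_EMPTY, REASON_SCATTER, REASON_MANUAL)

# Raster orders: how flat pixel index i maps onto the (ny, nx) image.
ROW_MAJOR = "row_major_top_left"        # row i // nx, column i % nx
COLUMN_MAJOR = "column_major_top_left"  # column i // ny, row i % ny


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid: number of spectra along x and y and raster order.

    The instrument records ``nx * ny`` spectra in a fixed scan order; only
    these two integers are needed to reshape per-pixel vectors into images.
    """

    nx: int
    ny: int
    raster_order: str = ROW_MAJOR

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ParameterError(f"grid dimensions must be >= 1, got nx={self.nx}, ny={self.ny}")
        if self.raster_order not in (ROW_MAJOR, COLUMN_MAJOR):
            raise ParameterError(f"unknown raster_order {self.raster_order!r}")

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny


def validate_axis(axis: np.ndarray) -> np.ndarray:
    """Return ``axis`` as a float array, enforcing the canonical form:
    strictly increasing, finite, positive wavenumbers in cm^-1."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise ParameterError("wavenumber axis must be one-dimensional")
    if axis.size and not np.all(np.isfinite(axis)):
        raise ParameterError("wavenumber axis contains non-finite values")
    if axis.size and np.any(axis <= 0):
        raise ParameterError("wavenumbers must be > 0")
    if axis.size > 1 and not np.all(np.diff(axis) > 0):
        raise ParameterError("wavenumber axis must be strictly increasing")
    return axis


@dataclass
class SpectralMap:
    """Dense absorbance matrix plus wavenumber axis and per-pixel sample ids.

    Parameters
    ----------
    absorbance
        ``(n_pixels, n_wavenumbers)`` array of absorbance values.
    axis
        Strictly ascending wavenumber axis, cm^-1, length ``n_wavenumbers``.
    grid
        Optional acquisition grid; if present, ``n_pixels == nx * ny``.
    sample_ids
        One identifier per pixel row; defaults to ``"sample"`` for all rows.
    log
        Plain-text provenance entries, appended to by every transform.
    """

    absorbance: np.ndarray
    axis: np.ndarray
    grid: Optional[GridSpec] = None
    sample_ids: Optional[np.ndarray] = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.axis = validate_axis(self.axis)
        if self.absorbance.shape[1] != self.axis.size:
            raise ShapeError(
                f"absorbance has {self.absorbance.shape[1]} columns but axis has "
                f"{self.axis.size} wavenumbers"
            )
        if self.grid is not None and self.absorbance.shape[0] != self.grid.n_pixels:
            raise ShapeError(
                f"map has {self.absorbance.shape[0]} pixels but grid is "
                f"{self.grid.nx} x {self.grid.ny} = {self.grid.n_pixels}"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array(["sample"] * self.n_pixels, dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (self.n_pixels,):
                raise ShapeError("sample_ids must have one entry per pixel row")
        if self.n_pixels and self.axis.size:
            if np.any(np.all(np.isnan(self.absorbance), axis=1)):
                raise ShapeError("a pixel row is entirely missing-valued")

    @property
    def n_pixels(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.absorbance.shape[1]

    def with_data(
        self,
        absorbance: Optional[np.ndarray] = None,
        axis: Optional[np.ndarray] = None,
        grid: object = "keep",
        sample_ids: Optional[np.ndarray] = None,
        log_entry: Optional[str] = None,
    ) -> "SpectralMap":
        """Return a copy with the given fields replaced and the provenance
        log extended by ``log_entry`` (if given)."""
        new = SpectralMap(
            absorbance=self.absorbance if absorbance is None else absorbance,
            axis=self.axis if axis is None else axis,
            grid=self.grid if grid == "keep" else grid,
            sample_ids=self.sample_ids if sample_ids is None else sample_ids,
            log=list(self.log),
        )
        if log_entry:
            new.log.append(log_entry)
        return new


@dataclass
class QCMask:
    """Per-pixel keep/exclude flags, in the ORIGINAL pixel order.

    ``reason`` holds a short code (``empty``, ``scatter``, ``manual``) for
    every excluded pixel and ``None`` for retained ones.  Masks compose by
    logical AND of ``keep``; on pixels both masks exclude, the first mask's
    reason wins (deterministic, documented tie-break).
    """

    keep: np.ndarray
    reason: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        if self.keep.ndim != 1 or self.reason.shape != self.keep.shape:
            raise MaskError("keep and reason must be 1-D arrays of equal length")
        for i in range(self.keep.size):
            if self.keep[i]:
                if self.reason[i] is not None:
                    raise MaskError(f"retained pixel {i} carries a reason code")
            elif self.reason[i] not in _VALID_REASONS:
                raise MaskError(f"excluded pixel {i} has invalid reason {self.reason[i]!r}")

    @classmethod
    def all_true(cls, n: int) -> "QCMask":
        return cls(np.ones(n, dtype=bool), np.array([None] * n, dtype=object))

    @classmethod
    def from_excluded(cls, n: int, excluded: Sequence[int], reason: str) -> "QCMask":
        keep = np.ones(n, dtype=bool)
        reasons = np.array([None] * n, dtype=object)
        idx = np.asarray(list(excluded), dtype=int)
        keep[idx] = False
        reasons[idx] = reason
        return cls(keep, reasons)

    @property
    def original_n(self) -> int:
        return self.keep.size

    @property
    def n_retained(self) -> int:
        return int(self.keep.sum())

    @property
    def excluded_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.keep)

    def combine(self, other: "QCMask") -> "QCMask":
        """AND-combine two masks; self's reason wins where both exclude."""
        if other.original_n != self.original_n:
            raise MaskError(
                f"cannot combine masks of length {self.original_n} and {other.original_n}"
            )
        keep = self.keep & other.keep
        reason = np.array([None] * self.original_n, dtype=object)
        for i in np.flatnonzero(~keep):
            reason[i] = self.reason[i] if not self.keep[i] else other.reason[i]
        return QCMask(keep, reason)

    def __and__(self, other: "QCMask") -> "QCMask":
        return self.combine(other)


@dataclass
class PCAResult:
    """Principal components of a spectral map.

    ``eigen_spectra`` rows are unit-norm loading vectors over the wavenumber
    axis ("eigen-spectra"); ``scores`` are the mean-centered projections of
    each pixel onto them.  The sign convention is that each eigen-spectrum's
    largest-magnitude entry is positive, making results reproducible across
    eigensolvers.
    """

    mean_spectrum: np.ndarray
    eigen_spectra: np.ndarray
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray
    axis: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigen_spectra.shape[0]


@dataclass
class ClusterAssignment:
    """Community labels per retained pixel, plus the parameters that made them.

    Labels are contiguous integers from 0, relabeled so that cluster 0 is
    the largest (ties broken by first-occurrence pixel index).  ``embedding``
    is an optional 2-D layout for visualization only; it never feeds the
    clustering itself.
    """

    labels: np.ndarray
    embedding: Optional[np.ndarray]
    params: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def n_pixels(self) -> int:
        return self.labels.size
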