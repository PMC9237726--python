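"""Per-pixel QC and spectral preprocessing.

Order of operations in the standard pipeline (each step optional but the
order is fixed): detect empty pixels and scatter outliers on the raw map,
apply the combined mask, excise the atmospheric CO2 region, vector-normalize
the retained spectra, then take the Savitzky-Golay second derivative.
Normalization runs only on retained spectra; CO2 excision precedes the
derivative and clustering so atmospheric variation cannot drive either.

QC detectors never modify the data: they return a :class:`QCMask` over the
ORIGINAL pixel order, so excluded positions can later be repopulated for
spatial mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.signal import savgol_filter

from .core import QCMask, REASON_EMPTY, REASON_SCATTER, SpectralMap
from .errors import (
    DegenerateSpectrumError,
    MaskError,
    ParameterError,
    SpacingError,
    WindowError,
)

__all__ = [
    "PreprocessParams",
    "detect_empty",
    "detect_scatter",
    "exclude_co2",
    "vector_normalize",
    "second_derivative",
    "apply_mask",
]


@dataclass
class PreprocessParams:
    """Tunable QC and preprocessing parameters.

    Defaults (all overridable):

    - ``empty_window`` 1600-1700 cm^-1 (amide I): a pixel whose mean
      absorbance there falls below ``empty_threshold`` (0.1) carries no
      tissue signal and is excluded as *empty*.
    - ``scatter_silent_window`` 1800-2600 cm^-1: biological tissue is
      nearly transparent here, so a large absolute baseline slope
      (> ``scatter_slope_threshold``, 1e-3 absorbance/cm^-1) indicates a
      scattering artifact.  A spectrum that is mostly negative (fraction
      above ``scatter_negative_fraction_threshold``, 0.6) is likewise
      flagged as *scatter*.
    - ``co2_window`` 2300-2400 cm^-1: the atmospheric CO2 asymmetric
      stretch, excised as a closed interval.
    - Savitzky-Golay second derivative: 9-point window, polynomial order 3.
    """

    empty_window: Tuple[float, float] = (1600.0, 1700.0)
    empty_threshold: float = 0.1
    scatter_silent_window: Tuple[float, float] = (1800.0, 2600.0)
    scatter_slope_threshold: float = 1e-3
    scatter_negative_fraction_threshold: float = 0.6
    co2_window: Tuple[float, float] = (2300.0, 2400.0)
    sg_window_pts: int = 9
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        for name in ("empty_window", "scatter_silent_window", "co2_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ParameterError(f"{name} must have lower < upper, got ({lo}, {hi})")
        for name in (
            "empty_threshold",
            "scatter_slope_threshold",
            "scatter_negative_fraction_threshold",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.scatter_negative_fraction_threshold > 1:
            raise ParameterError("scatter_negative_fraction_threshold must be in [0, 1]")
        if self.sg_window_pts < 5 or self.sg_window_pts % 2 == 0:
            raise ParameterError("sg_window_pts must be an odd integer >= 5")
        if not 2 <= self.sg_polyorder <= self.sg_window_pts - 1:
            raise ParameterError("sg_polyorder must be in [2, sg_window_pts - 1]")


def _window_columns(smap: SpectralMap, window: Tuple[float, float], what: str) -> np.ndarray:
    lo, hi = window
    cols = np.flatnonzero((smap.axis >= lo) & (smap.axis <= hi))
    if cols.size == 0:
        raise WindowError(
            f"{what} window [{lo}, {hi}] cm^-1 does not overlap the axis "
            f"({smap.axis[0]:g}-{smap.axis[-1]:g} cm^-1)"
        )
    return cols


def detect_empty(smap: SpectralMap, params: PreprocessParams | None = None) -> QCMask:
    """Flag pixels with no sample signal.

    A pixel is excluded (reason ``empty``) iff its mean absorbance inside
    ``empty_window`` is below ``empty_threshold``.
    """
    params = params or PreprocessParams()
    cols = _window_columns(smap, params.empty_window, "empty detection")
    means = smap.absorbance[:, cols].mean(axis=1)
    keep = means >= params.empty_threshold
    reason = np.where(keep, None, REASON_EMPTY).astype(object)
    return QCMask(keep, reason)


def detect_scatter(smap: SpectralMap, params: PreprocessParams | None = None) -> QCMask:
    """Flag scattering-artifact outlier spectra.

    A pixel is excluded (reason ``scatter``) iff the absolute least-squares
    slope of its absorbance over the silent window exceeds
    ``scatter_slope_threshold``, OR the fraction of negative absorbance
    values across its full spectrum exceeds
    ``scatter_negative_fraction_threshold``.
    """
    params = params or PreprocessParams()
    cols = _window_columns(smap, params.scatter_silent_window, "scatter detection")
    w = smap.axis[cols]
    a = smap.absorbance[:, cols]
    wc = w - w.mean()
    denom = float(np.sum(wc * wc))
    if denom == 0.0:
        slopes = np.zeros(smap.n_pixels)
    else:
        slopes = (a - a.mean(axis=1, keepdims=True)) @ wc / denom
    neg_frac = (smap.absorbance < 0).mean(axis=1)
    excluded = (np.abs(slopes) > params.scatter_slope_threshold) | (
        neg_frac > params.scatter_negative_fraction_threshold
    )
    keep = ~excluded
    reason = np.where(keep, None, REASON_SCATTER).astype(object)
    return QCMask(keep, reason)


def exclude_co2(smap: SpectralMap, params: PreprocessParams | None = None) -> SpectralMap:
    """Remove all wavenumbers inside the closed CO2 window.

    A window disjoint from the axis is a no-op; the operation is idempotent.
    """
    params = params or PreprocessParams()
    lo, hi = params.co2_window
    inside = (smap.axis >= lo) & (smap.axis <= hi)
    n_removed = int(inside.sum())
    if n_removed == 0:
        return smap.with_data(log_entry=f"exclude_co2: window [{lo}, {hi}] disjoint, no-op")
    keepc = ~inside
    return smap.with_data(
        absorbance=smap.absorbance[:, keepc],
        axis=smap.axis[keepc],
        log_entry=f"exclude_co2: removed {n_removed} points in [{lo}, {hi}] cm^-1",
    )


def vector_normalize(smap: SpectralMap) -> SpectralMap:
    """Scale every spectrum to unit Euclidean norm.

    Removes pathlength/concentration scaling so spectra compare by shape.
    The caller must have applied QC first: a zero-norm row (which should
    have been excluded as empty) raises :class:`DegenerateSpectrumError`.
    """
    norms = np.linalg.norm(smap.absorbance, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateSpectrumError(
            f"pixel {int(zero[0])} has zero norm; exclude empty pixels before normalizing"
        )
    return smap.with_data(
        absorbance=smap.absorbance / norms[:, None],
        log_entry="vector_normalize: rows scaled to unit Euclidean norm",
    )


def _uniform_segments(axis: np.ndarray, min_len: int) -> list:
    """Split the axis into maximal contiguous runs of uniform spacing.

    Gaps (e.g. left by CO2 excision) delimit segments; within a segment all
    spacings must agree with the segment's first spacing to 1e-6 relative.
    """
    n = axis.size
    if n < min_len:
        raise SpacingError(f"axis has {n} points; the filter window needs {min_len}")
    d = np.diff(axis)
    segments = []
    start = 0
    for i in range(1, n):
        h0 = d[start]
        if abs(d[i - 1] - h0) > 1e-6 * abs(h0):
            segments.append((start, i))
            start = i
    segments.append((start, n))
    # merge check: a segment produced by jitter (every diff different) shows
    # up as runs of length < min_len
    for s, e in segments:
        if e - s < min_len:
            raise SpacingError(
                "axis is not uniformly spaced (within 1e-6 relative) over runs "
                f"long enough for the {min_len}-point filter window"
            )
    return segments


def second_derivative(
    smap: SpectralMap, params: PreprocessParams | None = None
) -> SpectralMap:
    """Savitzky-Golay second derivative of each spectrum w.r.t. wavenumber.

    Annihilates constant and linear baseline components, controlling for
    baseline variation at acquisition time, and sharpens overlapping bands.
    Output units are absorbance * cm^2 (values scaled by spacing^-2); the
    axis is unchanged.  Edge regions are filled by evaluating the local
    polynomial fit at the edge points rather than truncating the axis.
    The axis must be uniformly spaced within each contiguous run; runs
    separated by gaps (e.g. after CO2 excision) are filtered independently.
    """
    params = params or PreprocessParams()
    segments = _uniform_segments(smap.axis, params.sg_window_pts)
    out = np.empty_like(smap.absorbance)
    for s, e in segments:
        h = float(smap.axis[s + 1] - smap.axis[s]) if e - s > 1 else 1.0
        out[:, s:e] = savgol_filter(
            smap.absorbance[:, s:e],
            window_length=params.sg_window_pts,
            polyorder=params.sg_polyorder,
            deriv=2,
            delta=h,
            axis=1,
            mode="interp",
        )
    return smap.with_data(
        absorbance=out,
        log_entry=(
            f"second_derivative: Savitzky-Golay window={params.sg_window_pts} "
            f"polyorder={params.sg_polyorder}, {len(segments)} uniform segment(s)"
        ),
    )


def apply_mask(smap: SpectralMap, mask: QCMask) -> SpectralMap:
    """Keep only retained rows, preserving original order.

    The grid is dropped from the result (it no longer matches the pixel
    count); keep the mask alongside for later repopulation.
    """
    if mask.original_n != smap.n_pixels:
        raise MaskError(
            f"mask covers {mask.original_n} pixels but map has {smap.n_pixels}"
        )
    return smap.with_data(
        absorbance=smap.absorbance[mask.keep],
        sample_ids=smap.sample_ids[mask.keep],
        grid=None,
        log_entry=f"apply_mask: retained {mask.n_retained} of {mask.original_n} pixels",
    )
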