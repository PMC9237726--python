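"""Reading and writing spectral matrices, annotations and QC masks.

On-disk interchange format is delimited text (comma or tab, auto-detected on
read), UTF-8, "." decimal separator.  Two orientations are supported:

``columns`` (default)
    Wavenumbers run down the first column; each subsequent column is one
    spectrum.  The header row is ``wavenumber,<sample_id>,...`` with one
    sample id per spectrum column.  A headerless variant (first row already
    numeric) is accepted on read.

``rows``
    The header row is ``sample_id,<w_1>,<w_2>,...`` and each subsequent row
    is one spectrum, prefixed by its sample id.

FTIR instruments commonly export descending wavenumber axes; the reader
reverses those to the package's canonical ascending order and records the
reversal in the provenance log.  No resampling ever happens at this layer:
joining samples requires identical axes.
"""

from __future__ import annotations

import os
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GridSpec, QCMask, SpectralMap
from .errors import AnnotationError, FormatError, IncompatibleAxesError

__all__ = [
    "read_spectral_table",
    "write_spectral_table",
    "concat_samples",
    "read_annotations",
    "pixel_annotations",
    "write_qc_mask",
    "read_qc_mask",
]

#: absolute tolerance (cm^-1) within which two axes count as identical
AXIS_ATOL = 1e-6


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _parse_float(token: str, where: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric value {token!r} in {where}") from None


def _read_rows(path: str) -> tuple[List[List[str]], str]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: file is empty")
    delim = _sniff_delimiter(lines[0])
    rows = [ln.split(delim) for ln in lines]
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i} has {len(row)} fields, expected {width}"
            )
    return rows, delim


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_spectral_table(
    path: str,
    orientation: str = "columns",
    grid: Optional[GridSpec] = None,
    sample_id: Optional[str] = None,
) -> SpectralMap:
    """Read a delimited-text spectral matrix into a :class:`SpectralMap`.

    Parameters
    ----------
    path
        Input file; delimiter (comma/tab) is auto-detected.
    orientation
        ``"columns"`` (wavenumbers down the first column, spectra in
        columns) or ``"rows"`` (axis in the header row, spectra in rows).
    grid
        Optional acquisition grid to attach (nx, ny are never read from the
        data file itself).
    sample_id
        If given, overrides any sample ids found in the file header.
    """
    if orientation not in ("columns", "rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    rows, _ = _read_rows(path)

    if orientation == "columns":
        header = rows[0]
        has_header = not _is_number(header[0])
        sids: Optional[List[str]] = None
        if has_header:
            sids = [str(s) for s in header[1:]]
            rows = rows[1:]
        if not rows:
            raise FormatError(f"{path}: no data rows")
        axis = np.array(
            [_parse_float(r[0], f"wavenumber column, data row {i}") for i, r in enumerate(rows)]
        )
        data = np.array(
            [
                [_parse_float(tok, f"data row {i}, column {j + 1}") for j, tok in enumerate(r[1:])]
                for i, r in enumerate(rows)
            ]
        ).T  # -> (n_pixels, n_wavenumbers)
    else:
        header = rows[0]
        axis = np.array(
            [_parse_float(tok, f"axis header, field {j + 1}") for j, tok in enumerate(header[1:])]
        )
        sids = [str(r[0]) for r in rows[1:]]
        data = np.array(
            [
                [_parse_float(tok, f"data row {i}, column {j + 1}") for j, tok in enumerate(r[1:])]
                for i, r in enumerate(rows[1:])
            ]
        )
        if data.size == 0:
            data = data.reshape(0, axis.size)

    log: List[str] = [f"read_spectral_table: {os.path.basename(path)} ({orientation})"]
    if axis.size > 1 and np.all(np.diff(axis) < 0):
        axis = axis[::-1].copy()
        data = data[:, ::-1].copy()
        log.append("axis reversed from descending to canonical ascending order")

    if sample_id is not None:
        sids = [sample_id] * data.shape[0]
    elif not sids or len(sids) != data.shape[0]:
        sids = [os.path.splitext(os.path.basename(path))[0]] * data.shape[0]

    try:
        return SpectralMap(data, axis, grid=grid, sample_ids=np.array(sids, dtype=object), log=log)
    except Exception as exc:  # surface axis problems as format errors
        raise FormatError(f"{path}: {exc}") from exc


def write_spectral_table(
    smap: SpectralMap, path: str, orientation: str = "columns", delimiter: str = ","
) -> None:
    """Write a :class:`SpectralMap` as delimited text, re-readable by
    :func:`read_spectral_table` with the same orientation."""
    if orientation not in ("columns", "rows"):
        raise FormatError(f"unknown orientation {orientation!r}")
    fmt = repr  # shortest representation that round-trips the float exactly
    with open(path, "w", encoding="utf-8") as fh:
        if orientation == "columns":
            fh.write(delimiter.join(["wavenumber"] + [str(s) for s in smap.sample_ids]) + "\n")
            for j in range(smap.n_wavenumbers):
                cells = [fmt(float(smap.axis[j]))] + [fmt(float(v)) for v in smap.absorbance[:, j]]
                fh.write(delimiter.join(cells) + "\n")
        else:
            fh.write(delimiter.join(["sample_id"] + [fmt(float(w)) for w in smap.axis]) + "\n")
            for i in range(smap.n_pixels):
                cells = [str(smap.sample_ids[i])] + [fmt(float(v)) for v in smap.absorbance[i]]
                fh.write(delimiter.join(cells) + "\n")


def concat_samples(
    maps: Sequence[SpectralMap], annotations: Optional[pd.DataFrame] = None
) -> SpectralMap:
    """Row-concatenate maps for joint analysis.

    Axes must be identical within ``AXIS_ATOL`` (no silent resampling);
    the first map's axis is kept.  If ``annotations`` is given, every
    sample id appearing in the maps must be covered by its ``sample_name``
    column.  Per-sample row order is preserved; grids are dropped (a joint
    map spans acquisitions).
    """
    if not maps:
        raise IncompatibleAxesError("concat_samples requires at least one map")
    ref = maps[0]
    for m in maps[1:]:
        if m.axis.size != ref.axis.size or np.any(np.abs(m.axis - ref.axis) > AXIS_ATOL):
            if m.axis.size != ref.axis.size:
                raise IncompatibleAxesError(
                    f"axis lengths differ: {ref.axis.size} vs {m.axis.size}"
                )
            k = int(np.argmax(np.abs(m.axis - ref.axis) > AXIS_ATOL))
            raise IncompatibleAxesError(
                f"axes differ at index {k}: {ref.axis[k]} vs {m.axis[k]} cm^-1"
            )
    if annotations is not None:
        known = set(map(str, annotations["sample_name"]))
        for m in maps:
            for sid in np.unique(m.sample_ids.astype(str)):
                if sid not in known:
                    raise AnnotationError(f"sample {sid!r} not present in annotation table")
    data = np.vstack([m.absorbance for m in maps])
    sids = np.concatenate([m.sample_ids for m in maps])
    log = [e for m in maps for e in m.log]
    log.append(f"concat_samples: joined {len(maps)} map(s), {data.shape[0]} pixels")
    return SpectralMap(data, ref.axis.copy(), grid=None, sample_ids=sids, log=log)


def read_annotations(path: str) -> pd.DataFrame:
    """Read a sample-level annotation table; a ``sample_name`` column is
    mandatory."""
    first = open(path, "r", encoding="utf-8").readline()
    df = pd.read_csv(path, sep=_sniff_delimiter(first))
    if "sample_name" not in df.columns:
        raise AnnotationError(f"{path}: annotation table lacks a 'sample_name' column")
    df["sample_name"] = df["sample_name"].astype(str)
    return df


def pixel_annotations(smap: SpectralMap, annotations: pd.DataFrame) -> pd.DataFrame:
    """Broadcast sample-level annotations to one record per pixel, in pixel
    order, by joining on sample name."""
    if "sample_name" not in annotations.columns:
        raise AnnotationError("annotation table lacks a 'sample_name' column")
    left = pd.DataFrame(
        {"pixel_index": np.arange(smap.n_pixels), "sample_name": smap.sample_ids.astype(str)}
    )
    merged = left.merge(annotations, on="sample_name", how="left", validate="many_to_one")
    if merged.drop(columns=["pixel_index", "sample_name"]).isna().all(axis=1).any():
        missing = sorted(
            set(left["sample_name"]) - set(annotations["sample_name"].astype(str))
        )
        if missing:
            raise AnnotationError(f"samples missing from annotation table: {missing}")
    return merged


def write_qc_mask(mask: QCMask, path: str) -> None:
    """Serialize a QC mask as delimited text: pixel_index, keep (0/1), reason."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pixel_index,keep,reason\n")
        for i in range(mask.original_n):
            reason = "" if mask.reason[i] is None else str(mask.reason[i])
            fh.write(f"{i},{int(mask.keep[i])},{reason}\n")


def read_qc_mask(path: str) -> QCMask:
    df = pd.read_csv(path, dtype={"reason": "string"})
    keep = df["keep"].to_numpy(dtype=bool)
    reason = np.array(
        [None if keep[i] else str(df["reason"].iloc[i]) for i in range(len(df))], dtype=object
    )
    return QCMask(keep, reason)
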