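"""Spatial reconstruction of per-pixel results in acquisition layout.

Excluded positions recorded in a :class:`~specmap.core.QCMask` are
repopulated with a missing marker, then the full-length vector is reshaped
onto the acquisition grid (declared raster order; default row-major,
origin top-left, x fastest).  Scalar maps use NaN as the missing marker;
label maps use -1.  Rendering writes a PNG plus a sidecar delimited-text
grid (missing as "NA") so maps stay machine-checkable bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import COLUMN_MAJOR, ClusterAssignment, GridSpec, QCMask, ROW_MAJOR, SpectralMap
from .errors import MaskError, ShapeError
from .quantify import BandWindow, integrate_band

__all__ = [
    "SpatialImage",
    "LABEL_MISSING",
    "repopulate",
    "to_grid",
    "map_band",
    "map_clusters",
    "write_image_text",
    "read_image_text",
    "render_png",
]

#: missing marker for label images (scalar images use NaN)
LABEL_MISSING = -1


@dataclass
class SpatialImage:
    """A (ny, nx) image of per-pixel scalars or cluster labels.

    ``kind`` is ``"scalar"`` (float values, missing = NaN) or ``"label"``
    (integer labels, missing = -1).  Every excluded original position holds
    the missing marker.
    """

    values: np.ndarray
    kind: str
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.kind not in ("scalar", "label"):
            raise ShapeError(f"unknown image kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ShapeError(
                f"image shape {self.values.shape} != grid (ny={self.grid.ny}, nx={self.grid.nx})"
            )

    @property
    def missing_marker(self):
        return np.nan if self.kind == "scalar" else LABEL_MISSING

    @property
    def missing(self) -> np.ndarray:
        if self.kind == "scalar":
            return np.isnan(self.values)
        return self.values == LABEL_MISSING

    def flatten(self) -> np.ndarray:
        """Inverse of :func:`to_grid` for the same raster order."""
        if self.grid.raster_order == COLUMN_MAJOR:
            return self.values.ravel(order="F")
        return self.values.ravel(order="C")


def repopulate(
    values: np.ndarray, mask: QCMask, missing: Union[float, int, None] = None
) -> np.ndarray:
    """Place per-retained-pixel values back at their original positions.

    Returns a vector of length ``mask.original_n`` with ``missing`` (NaN
    for float input, -1 for integer input, unless overridden) at every
    excluded position.  Pure index bookkeeping: retained values are copied
    bitwise.
    """
    values = np.asarray(values)
    if values.ndim != 1:
        raise MaskError("repopulate expects a 1-D value vector")
    if values.size != mask.n_retained:
        raise MaskError(
            f"{values.size} values for {mask.n_retained} retained pixels "
            f"(mask covers {mask.original_n})"
        )
    if np.issubdtype(values.dtype, np.integer):
        fill = LABEL_MISSING if missing is None else missing
        full = np.full(mask.original_n, fill, dtype=values.dtype)
    else:
        fill = np.nan if missing is None else missing
        full = np.full(mask.original_n, fill, dtype=float)
    full[mask.keep] = values
    return full


def to_grid(full_values: np.ndarray, grid: GridSpec, kind: str = "scalar") -> SpatialImage:
    """Reshape a full-length vector onto the acquisition grid.

    Row-major raster order maps pixel i to row ``i // nx``, column
    ``i % nx`` (origin top-left, x fastest); the column-major order maps
    i to column ``i // ny``, row ``i % ny``.
    """
    full_values = np.asarray(full_values)
    if full_values.size != grid.n_pixels:
        raise ShapeError(
            f"vector length {full_values.size} != nx*ny = {grid.nx}*{grid.ny} = {grid.n_pixels}"
        )
    if grid.raster_order == COLUMN_MAJOR:
        img = full_values.reshape(grid.nx, grid.ny).T
    else:
        img = full_values.reshape(grid.ny, grid.nx)
    return SpatialImage(values=img, kind=kind, grid=grid)


def map_band(
    smap: SpectralMap,
    mask: QCMask,
    grid: GridSpec,
    window: BandWindow,
    png_path: Optional[str] = None,
) -> SpatialImage:
    """Integrated band area mapped across the tissue.

    ``smap`` holds only the retained pixels (the mask's kept rows);
    integration runs on those, excluded positions are repopulated as NaN,
    and the result is rasterized onto the grid.  If ``png_path`` is given,
    a rendered image is written alongside.
    """
    quant = integrate_band(smap, window)
    image = to_grid(repopulate(quant.values, mask), grid, kind="scalar")
    if png_path is not None:
        render_png(image, png_path)
    return image


def map_clusters(
    labels: ClusterAssignment,
    mask: QCMask,
    grid: GridSpec,
    png_path: Optional[str] = None,
) -> SpatialImage:
    """Cluster classification mapped across the tissue (missing = -1)."""
    lab = labels.labels if isinstance(labels, ClusterAssignment) else np.asarray(labels, int)
    image = to_grid(repopulate(lab.astype(int), mask), grid, kind="label")
    if png_path is not None:
        render_png(image, png_path)
    return image


def write_image_text(image: SpatialImage, path: str, delimiter: str = ",") -> None:
    """Sidecar exact-value grid; missing written as "NA"."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={image.kind} nx={image.grid.nx} ny={image.grid.ny} "
                 f"raster={image.grid.raster_order}\n")
        miss = image.missing
        for r in range(image.grid.ny):
            cells = []
            for c in range(image.grid.nx):
                if miss[r, c]:
                    cells.append("NA")
                elif image.kind == "label":
                    cells.append(str(int(image.values[r, c])))
                else:
                    cells.append("%.12g" % image.values[r, c])
            fh.write(delimiter.join(cells) + "\n")


def read_image_text(path: str, delimiter: str = ",") -> SpatialImage:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        rows = [ln.strip().split(delimiter) for ln in fh if ln.strip()]
    kind = meta["kind"]
    grid = GridSpec(nx=int(meta["nx"]), ny=int(meta["ny"]), raster_order=meta["raster"])
    if kind == "label":
        vals = np.array(
            [[LABEL_MISSING if c == "NA" else int(c) for c in row] for row in rows], dtype=int
        )
    else:
        vals = np.array(
            [[np.nan if c == "NA" else float(c) for c in row] for row in rows], dtype=float
        )
    return SpatialImage(values=vals, kind=kind, grid=grid)


def render_png(image: SpatialImage, path: str) -> None:
    """Render the image to PNG.

    Scalar maps use a sequential colormap with missing pixels in a reserved
    color outside the colormap; label maps use categorical colors with a
    legend keyed by cluster label and a distinct color for missing.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colors as mcolors
    from matplotlib import patches as mpatches

    fig, ax = plt.subplots(figsize=(5, 5 * image.grid.ny / max(image.grid.nx, 1)))
    if image.kind == "scalar":
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad("#d62728")  # reserved missing color, outside the colormap
        shown = ax.imshow(np.ma.masked_invalid(image.values), cmap=cmap, origin="upper")
        fig.colorbar(shown, ax=ax, shrink=0.8)
    else:
        labels = sorted(int(v) for v in np.unique(image.values) if v != LABEL_MISSING)
        palette = plt.get_cmap("tab20").colors
        color_list = ["#bbbbbb"] + [palette[i % len(palette)] for i in range(len(labels))]
        lut = {LABEL_MISSING: 0, **{lab: i + 1 for i, lab in enumerate(labels)}}
        indexed = np.vectorize(lut.get)(image.values)
        cmap = mcolors.ListedColormap(color_list)
        ax.imshow(indexed, cmap=cmap, origin="upper", vmin=0, vmax=len(color_list) - 1)
        handles = [mpatches.Patch(color="#bbbbbb", label="excluded")] + [
            mpatches.Patch(color=color_list[i + 1], label=f"cluster {lab}")
            for i, lab in enumerate(labels)
        ]
        ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
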