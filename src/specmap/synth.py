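"""Ground-truthed synthetic FTIR tissue scenes.

A scene is a small hyperspectral phantom: a grid of pixels partitioned
into spatially contiguous region classes, each with a signature made of
Gaussian absorption bands (center cm^-1, amplitude, sigma), plus the
nuisance structure real focal-plane-array data carries — mild per-pixel
affine baselines, a variable atmospheric CO2 band, additive Gaussian
channel noise, sample holes (noise-only, near-zero spectra) and
scattering-artifact pixels with a steep rising baseline.  Every element is
recorded in the scene object, so the generative truth (region labels, hole
coordinates, band parameters) is available as an oracle for every pipeline
stage.  Rendering is seeded and bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import yaml

from .core import GridSpec, SpectralMap
from .errors import ConfigurationError, ParameterError

__all__ = [
    "GaussianBand",
    "SyntheticScene",
    "default_axis",
    "make_default_scene",
    "render",
    "save_scene",
    "load_scene",
    "CASE_PROTEIN_SIGNATURE",
]

#: atmospheric CO2 asymmetric stretch
CO2_CENTER = 2349.0
CO2_SIGMA = 12.0


@dataclass(frozen=True)
class GaussianBand:
    center: float
    amplitude: float
    sigma: float


# Region-class signatures for the default scene.  Band positions follow the
# standard biological assignments; amplitudes are in absorbance units typical
# of 4-10 um tissue sections.  Every class carries amide I/II (all tissue
# contains protein), so "no sample" is distinguishable from "little protein".
DEFAULT_SIGNATURES: Dict[int, List[GaussianBand]] = {
    0: [  # protein-rich (e.g. grey matter): strong amide I/II
        GaussianBand(1654.0, 1.00, 12.0),
        GaussianBand(1545.0, 0.60, 12.0),
        GaussianBand(1454.0, 0.15, 10.0),
        GaussianBand(2925.0, 0.20, 14.0),
    ],
    1: [  # lipid-rich (e.g. myelinated white matter): CH2 stretches + ester
        GaussianBand(2920.0, 0.90, 11.0),
        GaussianBand(2850.0, 0.55, 9.0),
        GaussianBand(1740.0, 0.30, 9.0),
        GaussianBand(1654.0, 0.60, 12.0),
        GaussianBand(1545.0, 0.35, 12.0),
        GaussianBand(1465.0, 0.15, 8.0),
    ],
    2: [  # nucleic-acid-rich (e.g. dense cellularity): PO2- stretches
        GaussianBand(1080.0, 0.70, 14.0),
        GaussianBand(1238.0, 0.40, 11.0),
        GaussianBand(1654.0, 0.65, 12.0),
        GaussianBand(1545.0, 0.40, 12.0),
        GaussianBand(965.0, 0.10, 8.0),
    ],
}

#: a "disease-like" protein signature: amide I shifted toward 1648 cm^-1
#: with an added beta-sheet component at 1628 cm^-1 (misfolding-like shift),
#: used by the case/control sample-set generator.
CASE_PROTEIN_SIGNATURE: List[GaussianBand] = [
    GaussianBand(1648.0, 0.85, 12.0),
    GaussianBand(1628.0, 0.35, 9.0),
    GaussianBand(1545.0, 0.55, 12.0),
    GaussianBand(1454.0, 0.15, 10.0),
    GaussianBand(2925.0, 0.20, 14.0),
]


@dataclass
class SyntheticScene:
    """Full generative specification of one synthetic tissue map.

    ``region_map``, ``holes`` and ``scatter_pixels`` index pixels in flat
    raster order (the grid's raster_order).  ``holes`` and
    ``scatter_pixels`` are disjoint; hole pixels render as noise-only
    near-zero spectra regardless of their region class.
    """

    grid: GridSpec
    region_map: np.ndarray
    class_signatures: Dict[int, List[GaussianBand]]
    holes: np.ndarray
    scatter_pixels: np.ndarray
    scatter_slopes: np.ndarray
    baseline_offset: np.ndarray
    baseline_slope: np.ndarray
    co2_amplitude: np.ndarray
    noise_sd: float
    seed: int
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        n = self.grid.n_pixels
        self.region_map = np.asarray(self.region_map, dtype=int)
        self.holes = np.asarray(self.holes, dtype=int)
        self.scatter_pixels = np.asarray(self.scatter_pixels, dtype=int)
        self.scatter_slopes = np.asarray(self.scatter_slopes, dtype=float)
        for name in ("baseline_offset", "baseline_slope", "co2_amplitude"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.region_map.shape != (n,):
            raise ConfigurationError("region_map must cover every grid pixel")
        for name in ("holes", "scatter_pixels"):
            idx = getattr(self, name)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ConfigurationError(f"{name} contains out-of-bounds pixel indices")
        if self.scatter_slopes.shape != self.scatter_pixels.shape:
            raise ConfigurationError("scatter_slopes must align with scatter_pixels")
        for cls in np.unique(self.region_map):
            if int(cls) not in self.class_signatures:
                raise ConfigurationError(f"region class {int(cls)} has no signature")

    @property
    def n_pixels(self) -> int:
        return self.grid.n_pixels


def default_axis() -> np.ndarray:
    """950-3100 cm^-1 at 2 cm^-1 spacing: fingerprint + CH-stretch regions."""
    return np.arange(950.0, 3100.0 + 1.0, 2.0)


def _region_bands(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Three contiguous vertical regions with seeded, gently wavy borders."""
    b1 = nx // 3
    b2 = (2 * nx) // 3
    region = np.empty((ny, nx), dtype=int)
    for r in range(ny):
        j1 = int(np.clip(b1 + rng.integers(-1, 2), 1, nx - 2))
        j2 = int(np.clip(b2 + rng.integers(-1, 2), j1 + 1, nx - 1))
        region[r, :j1] = 0
        region[r, j1:j2] = 1
        region[r, j2:] = 2
    return region.ravel()


def make_default_scene(nx: int = 32, ny: int = 32, seed: int = 0) -> SyntheticScene:
    """Default three-region scene: protein-, lipid- and nucleic-acid-rich
    tissue classes, ~2% holes, ~2% scatter pixels, mild affine baselines,
    variable atmospheric CO2 and Gaussian noise (sd 0.005 absorbance)."""
    if nx < 4 or ny < 4:
        raise ParameterError(f"grid must be at least 4 x 4, got {nx} x {ny}")
    grid = GridSpec(nx=nx, ny=ny)
    n = grid.n_pixels
    rng = np.random.default_rng([int(seed), 11])
    region_map = _region_bands(nx, ny, rng)
    n_holes = max(1, round(0.02 * n))
    n_scatter = max(1, round(0.02 * n))
    special = rng.choice(n, size=n_holes + n_scatter, replace=False)
    holes = np.sort(special[:n_holes])
    scatter_pixels = np.sort(special[n_holes:])
    return SyntheticScene(
        grid=grid,
        region_map=region_map,
        class_signatures={k: list(v) for k, v in DEFAULT_SIGNATURES.items()},
        holes=holes,
        scatter_pixels=scatter_pixels,
        scatter_slopes=rng.uniform(1.5e-3, 3.0e-3, size=n_scatter),
        baseline_offset=rng.uniform(0.01, 0.06, size=n),
        baseline_slope=rng.uniform(-2e-5, 2e-5, size=n),
        co2_amplitude=rng.uniform(0.0, 0.15, size=n),
        noise_sd=0.005,
        seed=int(seed),
    )


def _gaussian(axis: np.ndarray, band: GaussianBand) -> np.ndarray:
    return band.amplitude * np.exp(-0.5 * ((axis - band.center) / band.sigma) ** 2)


def render(scene: SyntheticScene, axis: np.ndarray | None = None) -> SpectralMap:
    """Render the scene to a :class:`SpectralMap` on the given axis.

    Each pixel is the sum of its class's Gaussian bands, its affine
    baseline (anchored at the axis midpoint), its CO2 contribution, a steep
    rising baseline for scatter pixels, and i.i.d. Gaussian channel noise.
    Hole pixels are rendered as noise only.  Rendering is deterministic in
    ``scene.seed``: repeated calls yield bitwise-identical maps.
    """
    axis = default_axis() if axis is None else np.asarray(axis, dtype=float)
    for cls, bands in scene.class_signatures.items():
        for band in bands:
            if not axis[0] <= band.center <= axis[-1]:
                raise ConfigurationError(
                    f"band center {band.center} cm^-1 of class {cls} lies outside the "
                    f"axis ({axis[0]:g}-{axis[-1]:g} cm^-1)"
                )
    n = scene.n_pixels
    class_spectra = {
        cls: sum(_gaussian(axis, b) for b in bands)
        for cls, bands in scene.class_signatures.items()
    }
    w_mid = 0.5 * (axis[0] + axis[-1])
    co2_shape = np.exp(-0.5 * ((axis - CO2_CENTER) / CO2_SIGMA) ** 2)

    data = np.empty((n, axis.size))
    for i in range(n):
        data[i] = class_spectra[int(scene.region_map[i])]
    data += scene.baseline_offset[:, None]
    data += scene.baseline_slope[:, None] * (axis - w_mid)[None, :]
    data += scene.co2_amplitude[:, None] * co2_shape[None, :]
    for k, i in enumerate(scene.scatter_pixels):
        data[i] += scene.scatter_slopes[k] * (axis - axis[0])
    data[scene.holes] = 0.0  # holes: no sample signal at all

    rng = np.random.default_rng([scene.seed, 97])
    if scene.noise_sd > 0:
        data += rng.normal(0.0, scene.noise_sd, size=data.shape)

    return SpectralMap(
        data,
        axis,
        grid=scene.grid,
        sample_ids=np.array([scene.sample_id] * n, dtype=object),
        log=[f"render: synthetic scene seed={scene.seed}, {n} pixels"],
    )


def save_scene(scene: SyntheticScene, path: str) -> None:
    """Write the scene specification as a YAML text config."""
    doc = {
        "nx": scene.grid.nx,
        "ny": scene.grid.ny,
        "raster_order": scene.grid.raster_order,
        "region_map": scene.region_map.tolist(),
        "class_signatures": {
            int(k): [[b.center, b.amplitude, b.sigma] for b in v]
            for k, v in scene.class_signatures.items()
        },
        "holes": scene.holes.tolist(),
        "scatter_pixels": scene.scatter_pixels.tolist(),
        "scatter_slopes": scene.scatter_slopes.tolist(),
        "baseline_offset": scene.baseline_offset.tolist(),
        "baseline_slope": scene.baseline_slope.tolist(),
        "co2_amplitude": scene.co2_amplitude.tolist(),
        "noise_sd": scene.noise_sd,
        "seed": scene.seed,
        "sample_id": scene.sample_id,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh)


def load_scene(path: str) -> SyntheticScene:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        return SyntheticScene(
            grid=GridSpec(nx=doc["nx"], ny=doc["ny"], raster_order=doc["raster_order"]),
            region_map=np.array(doc["region_map"]),
            class_signatures={
                int(k): [GaussianBand(*b) for b in v]
                for k, v in doc["class_signatures"].items()
            },
            holes=np.array(doc["holes"], dtype=int),
            scatter_pixels=np.array(doc["scatter_pixels"], dtype=int),
            scatter_slopes=np.array(doc["scatter_slopes"], dtype=float),
            baseline_offset=np.array(doc["baseline_offset"], dtype=float),
            baseline_slope=np.array(doc["baseline_slope"], dtype=float),
            co2_amplitude=np.array(doc["co2_amplitude"], dtype=float),
            noise_sd=float(doc["noise_sd"]),
            seed=int(doc["seed"]),
            sample_id=str(doc.get("sample_id", "synthetic")),
        )
    except KeyError as exc:
        raise ConfigurationError(f"scene config missing key {exc}") from exc


def make_sample_set(
    n_case: int = 3,
    n_control: int = 3,
    nx: int = 32,
    ny: int = 32,
    seed: int = 0,
) -> List[SyntheticScene]:
    """A small case/control study: control scenes use the default
    signatures; case scenes replace the protein-rich signature with a
    beta-sheet-shifted variant (amide I toward 1648 cm^-1 plus a 1628 cm^-1
    component), emulating a protein-misfolding pathology."""
    scenes = []
    for k in range(n_case + n_control):
        scene = make_default_scene(nx=nx, ny=ny, seed=int(seed) + k)
        if k < n_case:
            scene.class_signatures[0] = list(CASE_PROTEIN_SIGNATURE)
            scene.sample_id = f"case{k + 1}"
        else:
            scene.sample_id = f"control{k - n_case + 1}"
        scenes.append(scene)
    return scenes
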