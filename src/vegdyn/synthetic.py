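"""Labeled synthetic scenes for exercising the vegetation-change pipeline.

The generator produces monthly NDVI stacks whose per-pixel trends and
3x3 moving-window heterogeneity (CV) trends are known by construction,
plus annual driver rasters, land-cover and grassland-type maps, road and
river lines, and a ground-truth change-class raster.

Per-pixel generative model (growing-season month ``m`` of year ``t``,
years counted from the first year):

    v(t, m) = (b + s*t) * (1 + o * (A + d*t)) + eps + jitter

where ``b`` is the baseline NDVI, ``s`` the NDVI trend per year, ``o``
the pixel's fixed within-window offset (a zero-mean 3x3 pattern tiled
periodically, so every 3x3 window sees the full pattern), ``A``/``d``
the divergence amplitude and its trend, ``eps ~ N(0, noise_sd)`` the
per-observation error and ``jitter ~ N(0, noise_sd/2)`` the month-level
wobble. Because the pattern is zero-mean and periodic with period 3, the
window mean equals ``b + s*t`` and the window CV equals
``(A + d*t) * sd(pattern)`` in the noiseless limit — the NDVI trend and
the heterogeneity trend are controlled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
from shapely.geometry import LineString

from .containers import (
    AnnualStack,
    DRIVER_NAMES,
    DriverStack,
    GRASSLAND_LEGEND,
    LANDCOVER_LEGEND,
    MonthlyStack,
    RasterGrid,
)
from . import raster_io

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "OFFSET_PATTERN",
    "ScenarioSpec",
    "SyntheticScene",
    "simulate_pixel_series",
    "simulate_drivers",
    "build_scene",
    "demo_scene_specs",
    "DEFAULT_DRIVER_LINKS",
]

#: Integer codes of the change-class raster (0 = no significant change).
CLASS_CODES = {
    "not_significant": 0,
    "improving": 1,
    "regrowing": 2,
    "slight_degradation": 3,
    "medium_degradation": 4,
    "severe_degradation": 5,
    "desertification": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}
NODATA_CODE = -1

#: Canonical zero-mean 3x3 offset pattern; tiled periodically so every
#: 3x3 window contains all nine offsets (sample sd ~ 0.685).
OFFSET_PATTERN = np.array(
    [[-1.0, 0.25, -0.5],
     [0.75, 0.0, -0.75],
     [0.5, -0.25, 1.0]]
)

GROWING_SEASON = (5, 6, 7, 8, 9)

#: Required sign pattern per class: (ndvi_slope sign, divergence_slope
#: sign, baseline side of the 0.2 sparse-vegetation threshold).
_CLASS_CONSTRAINTS = {
    "improving": (1, -1, None),
    "regrowing": (1, 1, "sparse"),
    "slight_degradation": (1, 1, "vegetated"),
    "medium_degradation": (-1, 1, None),
    "severe_degradation": (-1, -1, "vegetated"),
    "desertification": (-1, -1, "sparse"),
    "no_change": (0, 0, None),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative parameters for one rectangular block of the scene.

    ``block`` is (row0, col0, n_rows, n_cols); blocks must be disjoint.
    """

    class_label: str
    block: tuple[int, int, int, int]
    baseline_ndvi: float
    ndvi_slope: float
    divergence_base: float
    divergence_slope: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in _CLASS_CONSTRAINTS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.divergence_base < 0:
            raise ValueError("divergence_base must be >= 0")
        if not 0 <= self.baseline_ndvi <= 1:
            raise ValueError("baseline_ndvi must lie in [0, 1]")

    def validate(self, n_years: int) -> None:
        """Check label/parameter consistency over an ``n_years`` horizon.

        Enforces (i) the sign pattern of the class, (ii) the sparse /
        vegetated side of the 0.2 threshold for both the baseline and
        the period-mean NDVI, (iii) the noiseless trajectory staying in
        [0, 1] at the extreme offsets, (iv) a non-negative divergence
        amplitude, and (v) preservation of the NDVI trend sign at every
        offset — so that a noiseless scene classifies to its label.
        """
        s_sign, d_sign, side = _CLASS_CONSTRAINTS[self.class_label]
        if np.sign(self.ndvi_slope) != s_sign or np.sign(self.divergence_slope) != d_sign:
            raise ValueError(
                f"{self.class_label}: slope signs ({self.ndvi_slope}, "
                f"{self.divergence_slope}) inconsistent with label"
            )
        t = np.arange(n_years, dtype=float)
        b = self.baseline_ndvi + self.ndvi_slope * t
        amp = self.divergence_base + self.divergence_slope * t
        mean_ndvi = b.mean()
        if side == "sparse" and not (self.baseline_ndvi < 0.2 and mean_ndvi < 0.2):
            raise ValueError(f"{self.class_label}: baseline and period-mean NDVI must be < 0.2")
        if side == "vegetated" and not (self.baseline_ndvi >= 0.2 and mean_ndvi >= 0.2):
            raise ValueError(f"{self.class_label}: baseline and period-mean NDVI must be >= 0.2")
        if np.any(amp < 0):
            raise ValueError("divergence amplitude becomes negative within the horizon")
        for o in (-1.0, 1.0):
            traj = b * (1 + o * amp)
            if traj.min() < 0 or traj.max() > 1:
                raise ValueError("noiseless trajectory exits [0, 1]")
            if self.ndvi_slope != 0 and n_years > 1:
                diffs = np.diff(traj)
                if np.any(np.sign(diffs) != np.sign(self.ndvi_slope)):
                    raise ValueError(
                        f"{self.class_label}: NDVI trend sign not preserved at "
                        f"offset {o:+.0f} (divergence trend too strong)"
                    )


def simulate_pixel_series(
    spec: ScenarioSpec,
    pattern_offset: float,
    years,
    months_per_year: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Monthly NDVI series for one pixel; shape (n_years, months_per_year)."""
    if not -1 <= pattern_offset <= 1:
        raise ValueError("pattern_offset must lie in [-1, 1]")
    years = np.asarray(years)
    t = (years - years[0]).astype(float)
    base = spec.baseline_ndvi + spec.ndvi_slope * t
    amp = spec.divergence_base + spec.divergence_slope * t
    noiseless = base * (1 + pattern_offset * amp)
    if noiseless.min() < 0 or noiseless.max() > 1:
        raise ValueError("noiseless trajectory exits [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (len(t), months_per_year)
    series = np.broadcast_to(noiseless[:, None], shape).copy()
    if spec.noise_sd > 0:
        series += rng.normal(0, spec.noise_sd, shape)
        series += rng.normal(0, spec.noise_sd / 2, shape)
    return np.clip(series, -1.0, 1.0)


@dataclass
class SyntheticScene:
    """A fully labeled synthetic input bundle on one grid."""

    monthly_ndvi: MonthlyStack
    drivers: DriverStack
    grassland_type: np.ndarray  # int raster, GRASSLAND_LEGEND codes
    landcover: np.ndarray  # int raster, LANDCOVER_LEGEND codes
    lines: list[LineString]
    truth: np.ndarray  # int raster, CLASS_CODES (+ NODATA_CODE)
    seed: int
    specs: list[ScenarioSpec] = field(default_factory=list)

    @property
    def grid(self) -> RasterGrid:
        return self.monthly_ndvi.grid

    def write(self, outdir) -> None:
        """Write the scene as TIFF+sidecar rasters, GeoJSON lines, and a
        JSON manifest recording the seed and every block's parameters."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        grid = self.grid
        raster_io.write_stack(self.monthly_ndvi, outdir / "ndvi_monthly.tif")
        for name, arr in self.drivers.variables.items():
            raster_io.write_raster(
                outdir / f"driver_{name}.tif", arr, grid,
                index=[[y] for y in self.drivers.years],
            )
        raster_io.write_raster(outdir / "grassland_type.tif", self.grassland_type, grid, dtype=np.int16)
        raster_io.write_raster(outdir / "landcover.tif", self.landcover, grid, dtype=np.int16)
        raster_io.write_raster(outdir / "truth.tif", self.truth, grid, dtype=np.int16)
        raster_io.write_lines_geojson(self.lines, outdir / "lines.geojson")
        manifest = {
            "seed": self.seed,
            "years": list(self.drivers.years),
            "grid": grid.to_dict(),
            "specs": [asdict(s) for s in self.specs],
            "legends": {
                "landcover": LANDCOVER_LEGEND,
                "grassland": GRASSLAND_LEGEND,
                "classes": CLASS_CODES,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


DEFAULT_COARSE_FACTOR = 4

#: Per-variable (mean, slope per year, noise sd) of the annual driver
#: fields, in their native units. Values emulate a semi-arid alpine
#: setting: ~450 mm precipitation rising slowly, slight warming, stable
#: humidity, mild wetting (SPEI), declining grazing pressure, and a
#: small, nearly static population count per cell.
DEFAULT_DRIVER_LINKS = {
    "Pre": {"mean": 450.0, "slope": 1.5, "sd": 30.0},
    "Temp": {"mean": 0.5, "slope": 0.03, "sd": 0.3},
    "RH": {"mean": 55.0, "slope": 0.05, "sd": 2.0},
    "SPEI": {"mean": 0.0, "slope": 0.01, "sd": 0.5},
    "Graz": {"mean": 50.0, "slope": -0.4, "sd": 5.0},
    "Pop": {"mean": 10.0, "slope": 0.0, "sd": 0.15},
}


def simulate_drivers(
    grid: RasterGrid,
    years,
    links: dict | None = None,
    response_link: dict[str, float] | None = None,
    seed: int = 0,
    coarse_factor: int = DEFAULT_COARSE_FACTOR,
) -> tuple[DriverStack, np.ndarray | None]:
    """Simulate the six annual driver rasters on a coarser grid and
    align them to ``grid``.

    Each variable is ``mean + slope*t + N(0, sd)`` per coarse pixel and
    year. ``Pop`` is rounded to whole persons per cell and aligned by
    nearest-neighbour (a count, not a field); the continuous variables
    are aligned bilinearly. If ``response_link`` maps variable names to
    coefficients, the second return value is the implied annual NDVI
    anomaly ``sum_v beta_v * z_v`` (per-pixel z-scores over years), to
    be added to a scene's NDVI so attribution is recoverable.
    """
    years = [int(y) for y in years]
    links = dict(DEFAULT_DRIVER_LINKS, **(links or {}))
    for name in links:
        if name not in DRIVER_NAMES:
            raise ValueError(f"unknown driver variable {name!r}")
        if links[name]["sd"] < 0:
            raise ValueError(f"{name}: negative sd")
    rng = np.random.default_rng(seed)
    t = np.arange(len(years), dtype=float)
    cg = RasterGrid(
        n_rows=-(-grid.n_rows // coarse_factor),
        n_cols=-(-grid.n_cols // coarse_factor),
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        pixel_size=grid.pixel_size * coarse_factor,
        crs_id=grid.crs_id,
        nodata=grid.nodata,
    )
    variables: dict[str, np.ndarray] = {}
    for name in DRIVER_NAMES:
        p = links[name]
        coarse = (
            p["mean"]
            + p["slope"] * t[:, None, None]
            + rng.normal(0, p["sd"], (len(years), cg.n_rows, cg.n_cols))
        )
        if name == "Pop":
            coarse = np.clip(np.rint(coarse), 0, None)
            fine = raster_io.align_to_grid(coarse, cg, grid, method="nearest")
        else:
            fine = raster_io.align_to_grid(coarse, cg, grid, method="bilinear")
        variables[name] = fine
    stack = DriverStack(grid, years, variables)
    anomaly = None
    if response_link:
        anomaly = np.zeros((len(years), grid.n_rows, grid.n_cols))
        for name, beta in response_link.items():
            v = stack.variables[name]
            mu = v.mean(axis=0, keepdims=True)
            sd = v.std(axis=0, keepdims=True)
            z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
            anomaly += beta * z
    return stack, anomaly


def _default_lines(grid: RasterGrid, specs: list[ScenarioSpec]) -> list[LineString]:
    # one road crossing the grid horizontally through the first block,
    # one river running diagonally; coordinates are map units
    px = grid.pixel_size
    if specs:
        r0, c0, nr, nc = specs[0].block
        row = r0 + nr // 2
    else:
        row = grid.n_rows // 2
    y_road = grid.origin_y - (row + 0.5) * px
    road = LineString([
        (grid.origin_x, y_road),
        (grid.origin_x + grid.n_cols * px, y_road),
    ])
    river = LineString([
        (grid.origin_x + 0.1 * grid.n_cols * px, grid.origin_y),
        (grid.origin_x + 0.9 * grid.n_cols * px, grid.origin_y - grid.n_rows * px),
    ])
    return [road, river]


def build_scene(
    specs: list[ScenarioSpec],
    grid: RasterGrid,
    years,
    seed: int = 0,
    background: ScenarioSpec | None = None,
    months: tuple[int, ...] = GROWING_SEASON,
    lines: list[LineString] | str | None = "default",
    water_fraction: float = 0.01,
    driver_links: dict | None = None,
    response_link: dict[str, float] | None = None,
    coarse_factor: int = DEFAULT_COARSE_FACTOR,
) -> SyntheticScene:
    """Assemble a full synthetic scene from block scenarios.

    Pixels not covered by any block follow ``background`` (default: a
    stable no-change surface with the blocks' noise level). A square
    water patch occupying ``water_fraction`` of the grid is carved into
    the land cover at the bottom-right corner; grassland type splits the
    grid into a steppe (left) and meadow (right) half.
    """
    years = [int(y) for y in years]
    if len(years) < 3:
        raise ValueError("need at least 3 years")
    occupancy = np.zeros(grid.shape, dtype=bool)
    for spec in specs:
        r0, c0, nr, nc = spec.block
        if r0 < 0 or c0 < 0 or r0 + nr > grid.n_rows or c0 + nc > grid.n_cols:
            raise ValueError(f"block {spec.block} exceeds the grid")
        if occupancy[r0:r0 + nr, c0:c0 + nc].any():
            raise ValueError(f"block {spec.block} overlaps another block")
        occupancy[r0:r0 + nr, c0:c0 + nc] = True
        spec.validate(len(years))
    if background is None:
        noise = specs[0].noise_sd if specs else 0.0
        background = ScenarioSpec(
            "no_change", (0, 0, grid.n_rows, grid.n_cols),
            baseline_ndvi=0.35, ndvi_slope=0.0,
            divergence_base=0.10, divergence_slope=0.0, noise_sd=noise,
        )
    background.validate(len(years))

    rng = np.random.default_rng(seed)
    t = np.arange(len(years), dtype=float)
    n_rows, n_cols = grid.shape

    # per-pixel generative parameter fields
    b = np.full(grid.shape, background.baseline_ndvi)
    s = np.full(grid.shape, background.ndvi_slope)
    A = np.full(grid.shape, background.divergence_base)
    d = np.full(grid.shape, background.divergence_slope)
    nsd = np.full(grid.shape, background.noise_sd)
    truth = np.zeros(grid.shape, dtype=np.int16)
    for spec in specs:
        r0, c0, nr, nc = spec.block
        sl = (slice(r0, r0 + nr), slice(c0, c0 + nc))
        b[sl], s[sl] = spec.baseline_ndvi, spec.ndvi_slope
        A[sl], d[sl] = spec.divergence_base, spec.divergence_slope
        nsd[sl] = spec.noise_sd
        truth[sl] = CLASS_CODES.get(spec.class_label, 0)

    reps = (n_rows // 3 + 1, n_cols // 3 + 1)
    offsets = np.tile(OFFSET_PATTERN, reps)[:n_rows, :n_cols]

    base_t = b[None] + s[None] * t[:, None, None]
    amp_t = A[None] + d[None] * t[:, None, None]
    annual = base_t * (1 + offsets[None] * amp_t)

    drivers, anomaly = simulate_drivers(
        grid, years, links=driver_links, response_link=response_link,
        seed=int(rng.integers(2**31)), coarse_factor=coarse_factor,
    )
    if anomaly is not None:
        annual = annual + anomaly

    n_months = len(months)
    shape = (len(years), n_months, n_rows, n_cols)
    monthly = np.repeat(annual[:, None], n_months, axis=1)
    monthly += rng.normal(0, 1.0, shape) * nsd[None, None]
    monthly += rng.normal(0, 1.0, shape) * (nsd[None, None] / 2)
    monthly = np.clip(monthly, -1.0, 1.0)

    # land cover: grassland everywhere except a water patch bottom-right
    landcover = np.ones(grid.shape, dtype=np.int16)
    if water_fraction > 0:
        side = max(1, int(round(np.sqrt(water_fraction * n_rows * n_cols))))
        landcover[n_rows - side:, n_cols - side:] = 3  # water
    masked = landcover != 1
    monthly[:, :, masked] = np.nan
    truth[masked] = NODATA_CODE

    grassland = np.where(
        np.arange(n_cols)[None, :] < n_cols // 2, 1, 2
    ).astype(np.int16) * np.ones((n_rows, 1), dtype=np.int16)

    if lines == "default":
        lines = _default_lines(grid, specs)
    elif lines is None:
        lines = []

    index = [(y, m) for y in years for m in months]
    values = monthly.reshape(len(years) * n_months, n_rows, n_cols)
    stack = MonthlyStack(grid, index, values)
    return SyntheticScene(
        monthly_ndvi=stack,
        drivers=drivers,
        grassland_type=grassland,
        landcover=landcover,
        lines=list(lines),
        truth=truth,
        seed=seed,
        specs=list(specs),
    )


def demo_scene_specs(noise_sd: float = 0.02, grid_size: int = 120) -> list[ScenarioSpec]:
    """The bundled six-block demo layout (default: a 120x120 grid).

    One 30x30 block per change class, arranged in two rows of three,
    with trend magnitudes typical of multi-decadal grassland records
    (|NDVI slope| 0.003-0.004/yr) and divergence trends sized, via a
    design-time power analysis, so each class is detectable at the
    default noise level. Smaller or larger grids scale the layout
    proportionally (blocks never drop below 6x6).
    """
    scale = grid_size / 120.0
    side = max(6, round(30 * scale))
    blocks = [(10, 5), (10, 45), (10, 85), (70, 5), (70, 45), (70, 85)]
    blocks = [
        (min(round(r * scale), grid_size - side), min(round(c * scale), grid_size - side))
        for r, c in blocks
    ]
    params = [
        ("improving", 0.45, 0.004, 0.15, -0.005),
        ("regrowing", 0.10, 0.004, 0.10, 0.010),
        ("slight_degradation", 0.50, 0.004, 0.08, 0.004),
        ("medium_degradation", 0.50, -0.004, 0.10, 0.005),
        ("severe_degradation", 0.55, -0.004, 0.15, -0.005),
        ("desertification", 0.19, -0.003, 0.30, -0.007),
    ]
    return [
        ScenarioSpec(label, (r0, c0, side, side), b, s, A, d, noise_sd)
        for (r0, c0), (label, b, s, A, d) in zip(blocks, params)
    ]
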