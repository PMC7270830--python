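"""Synthetic spaced-plant field trial with full ground truth.

Emulates the imaging geometry of a large perennial-ryegrass genomic
selection trial: 50 entries x 10 replicate plots in a randomized complete
block design, each plot 8 x 1.8 m holding 3 rows of 32 spaced plants
(25 cm within-row, 60 cm between-row spacing), imaged at 2 cm/pixel with
reflectance panels (6/11/22/33 %) and 9 ground-control markers in the
margins, plus a six-sonar ground vehicle logging ultrasonic ranges from a
bar 0.6 m above ground.

Blocks are stacked vertically (north to south), separated by bare-soil
alleys; each block holds one replicate plot of every entry side by side,
so plant rows form evenly pitched vertical strips.  Plants render as
isotropic Gaussian reflectance blobs (radius = 2 sigma) whose peak NDVI
is the plant's true NDVI; soil NDVI is drawn uniform in [0.05, 0.15] so
the projection profiles always see trough contrast.

Everything is deterministic for a fixed layout seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import utm
from .biomass import SeasonModel, predict_dmy
from .geo import Affine, BAND_WAVELENGTHS, MultibandRaster

__all__ = [
    "TrialLayout",
    "SensorRig",
    "LayoutError",
    "generate_layout",
    "render_ortho",
    "simulate_height_track",
    "simulate_harvest",
    "PanelSpec",
]

SOIL_NDVI_RANGE = (0.05, 0.15)
PLANT_NDVI_RANGE = (0.40, 0.90)
PLANT_HEIGHT_RANGE_CM = (8.0, 40.0)
# within-entry (plant-to-plant) half-ranges; entry means are drawn so that
# plant values stay inside the global ranges.  Breeding entries differ
# genetically, so most trait variance sits between entries.
ENTRY_NDVI_SPREAD = 0.06
ENTRY_HEIGHT_SPREAD_CM = 6.0
PANEL_REFLECTANCES_PCT = (6.0, 11.0, 22.0, 33.0)
PANEL_SIZE_M = 0.5
GCP_MARKER_SIZE_M = 0.5
# total reflectance (red + nir) of every surface; fixing it makes band
# reflectance an exact function of the NDVI ground truth
TOTAL_RED_NIR = 0.5


class LayoutError(ValueError):
    """Invalid trial-layout configuration."""


@dataclass(frozen=True)
class TrialLayout:
    """Geometry and design of the spaced-plant trial."""

    n_entries: int = 50
    n_reps: int = 10
    rows_per_plot: int = 3
    plants_per_row: int = 32
    plant_spacing: float = 0.25
    row_spacing: float = 0.60
    plot_length: float = 8.0
    plot_width: float = 1.8
    n_blocks: int = 10
    gsd: float = 0.02
    block_alley: float = 1.0
    margin: float = 3.0
    plant_radius: float = 0.12
    rng_seed: int = 0
    # world placement: top-left raster corner in UTM metres
    utm_zone: int = 54
    utm_south: bool = True
    origin_x: float = 594000.0
    origin_y: float = 5810900.0

    def __post_init__(self):
        for name in (
            "n_entries", "n_reps", "rows_per_plot", "plants_per_row",
            "n_blocks",
        ):
            if getattr(self, name) < 1:
                raise LayoutError(f"{name} must be >= 1")
        if self.plants_per_row * self.plant_spacing > self.plot_length + 1e-9:
            raise LayoutError(
                "plants_per_row * plant_spacing exceeds plot_length"
            )
        if self.rows_per_plot * self.row_spacing > self.plot_width + 1e-9:
            raise LayoutError("rows_per_plot * row_spacing exceeds plot_width")
        if self.n_reps != self.n_blocks:
            raise LayoutError(
                "randomized complete block design requires n_reps == n_blocks"
            )
        if self.gsd <= 0:
            raise LayoutError("gsd must be positive")

    # --- derived counts -------------------------------------------------
    @property
    def n_plots(self) -> int:
        return self.n_entries * self.n_reps

    @property
    def n_rows(self) -> int:
        return self.n_plots * self.rows_per_plot

    @property
    def n_plants(self) -> int:
        return self.n_rows * self.plants_per_row

    @property
    def rows_per_block(self) -> int:
        return self.n_entries * self.rows_per_plot

    # --- derived geometry (image-frame metres; x right, y down) --------
    @property
    def field_width(self) -> float:
        return self.rows_per_block * self.row_spacing

    @property
    def field_height(self) -> float:
        return (
            self.n_blocks * self.plot_length
            + (self.n_blocks - 1) * self.block_alley
        )

    @property
    def raster_width_px(self) -> int:
        return int(round((self.field_width + 2 * self.margin) / self.gsd))

    @property
    def raster_height_px(self) -> int:
        return int(round((self.field_height + 2 * self.margin) / self.gsd))

    @property
    def crs(self) -> str:
        return utm.epsg_for_zone(self.utm_zone, self.utm_south)

    @property
    def transform(self) -> Affine:
        return Affine(self.origin_x, self.origin_y, self.gsd, -self.gsd)

    def block_y0(self, block: int) -> float:
        """Image-frame y (m) of the top of a block band."""
        return self.margin + block * (self.plot_length + self.block_alley)

    def field_bbox(self):
        """Image-frame (x0, y0, x1, y1) metres of the trial area."""
        return (
            self.margin,
            self.margin,
            self.margin + self.field_width,
            self.margin + self.field_height,
        )


@dataclass(frozen=True)
class SensorRig:
    """Ultrasonic sensor bar of the ground vehicle."""

    n_sensors: int = 6
    lateral_offsets: tuple = (-0.75, -0.45, -0.15, 0.0, 0.30, 0.60)
    mount_height: float = 0.6
    sample_rate: float = 10.0
    speed: float = 1.0
    range_noise_sd: float = 0.0

    def __post_init__(self):
        if self.mount_height <= 0:
            raise LayoutError("mount_height must be positive")
        if len(self.lateral_offsets) != self.n_sensors:
            raise LayoutError("one lateral offset per sensor required")
        if len(set(self.lateral_offsets)) != self.n_sensors:
            raise LayoutError("lateral offsets must be distinct")


@dataclass(frozen=True)
class PanelSpec:
    reflectance_pct: float
    box_px: tuple  # (col0, row0, col1, row1), half-open


def generate_layout(layout: TrialLayout):
    """Randomize entries to plots and lay out every plant.

    Returns ``(plants, rows, plots)`` DataFrames.  Entries are assigned by
    an independent permutation per block (randomized complete block);
    plant IDs encode block / plot-position / row / position.  Coordinates
    are image-frame metres (``x``/``y``, y down from the raster top-left)
    and world UTM metres (``world_x``/``world_y``).
    """
    rng = np.random.default_rng(layout.rng_seed)
    ndvi_rng = np.random.default_rng(rng.integers(2**31))
    height_rng = np.random.default_rng(rng.integers(2**31))

    # entry-level trait means: cultivars/breeding lines differ genetically
    entry_ndvi_mu = ndvi_rng.uniform(
        PLANT_NDVI_RANGE[0] + ENTRY_NDVI_SPREAD,
        PLANT_NDVI_RANGE[1] - ENTRY_NDVI_SPREAD,
        size=layout.n_entries,
    )
    entry_height_mu = height_rng.uniform(
        PLANT_HEIGHT_RANGE_CM[0] + ENTRY_HEIGHT_SPREAD_CM,
        PLANT_HEIGHT_RANGE_CM[1] - ENTRY_HEIGHT_SPREAD_CM,
        size=layout.n_entries,
    )

    plot_rows, row_rows, plant_rows = [], [], []
    for b in range(layout.n_blocks):
        entries = rng.permutation(layout.n_entries) + 1
        y0 = layout.block_y0(b)
        for p in range(layout.n_entries):
            entry = int(entries[p])
            plot_id = f"B{b + 1:02d}-P{p + 1:02d}"
            px0 = layout.margin + p * layout.plot_width
            plot_rows.append(
                dict(
                    plot_id=plot_id, block=b + 1, plot_index=p + 1,
                    entry=entry, x0=px0, y0=y0,
                    x1=px0 + layout.plot_width, y1=y0 + layout.plot_length,
                )
            )
            for r in range(layout.rows_per_plot):
                gr = p * layout.rows_per_plot + r  # row index within block
                cx = layout.margin + (gr + 0.5) * layout.row_spacing
                row_id = f"B{b + 1:02d}R{gr + 1:03d}"
                row_rows.append(
                    dict(
                        row_id=row_id, plot_id=plot_id, block=b + 1,
                        row_in_block=gr + 1, row_in_plot=r + 1, entry=entry,
                        center_x=cx, y0=y0, y1=y0 + layout.plot_length,
                    )
                )
                n = layout.plants_per_row
                mu_n = entry_ndvi_mu[entry - 1]
                mu_h = entry_height_mu[entry - 1]
                ndvis = ndvi_rng.uniform(
                    mu_n - ENTRY_NDVI_SPREAD, mu_n + ENTRY_NDVI_SPREAD, size=n
                )
                heights = height_rng.uniform(
                    mu_h - ENTRY_HEIGHT_SPREAD_CM,
                    mu_h + ENTRY_HEIGHT_SPREAD_CM,
                    size=n,
                )
                for i in range(n):
                    cy = y0 + (i + 0.5) * layout.plant_spacing
                    plant_rows.append(
                        dict(
                            plant_id=f"{row_id}P{i + 1:02d}",
                            entry=entry, plot_id=plot_id, row_id=row_id,
                            block=b + 1, row_in_block=gr + 1,
                            position=i + 1, x=cx, y=cy,
                            radius=layout.plant_radius,
                            true_ndvi=float(ndvis[i]),
                            true_height_cm=float(heights[i]),
                        )
                    )
    plants = pd.DataFrame(plant_rows)
    t = layout.transform
    wx, wy = t.forward(plants["x"] / layout.gsd, plants["y"] / layout.gsd)
    plants["world_x"] = wx
    plants["world_y"] = wy
    return plants, pd.DataFrame(row_rows), pd.DataFrame(plot_rows)


def _ndvi_field(plants: pd.DataFrame, layout: TrialLayout, rng) -> np.ndarray:
    """Per-pixel ground-truth NDVI: soil texture plus Gaussian plant blobs."""
    h, w = layout.raster_height_px, layout.raster_width_px
    ndvi = rng.uniform(*SOIL_NDVI_RANGE, size=(h, w)).astype(np.float64)
    gsd = layout.gsd
    sigma_px = (layout.plant_radius / 2.0) / gsd
    reach = max(1, int(math.ceil(3 * sigma_px)))
    cols = plants["x"].to_numpy() / gsd
    rows_ = plants["y"].to_numpy() / gsd
    peaks = plants["true_ndvi"].to_numpy()
    # paint each blob into its local window; overlapping blobs combine by
    # max so each peak keeps exactly its plant's NDVI
    for c, r, peak in zip(cols, rows_, peaks):
        ic, ir = int(round(c)), int(round(r))
        c0, c1 = max(0, ic - reach), min(w, ic + reach + 1)
        r0, r1 = max(0, ir - reach), min(h, ir + reach + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (xx + 0.5 - c) ** 2 + (yy + 0.5 - r) ** 2
        wgt = np.exp(-d2 / (2 * sigma_px**2))
        patch = ndvi[r0:r1, c0:c1]
        cand = patch + (peak - patch) * wgt
        np.maximum(patch, cand, out=patch)
        # the pixel sampling the blob centre carries the exact peak NDVI
        if 0 <= ir < h and 0 <= ic < w:
            ndvi[ir, ic] = max(ndvi[ir, ic], peak)
    return ndvi


def _reflectance_from_ndvi(ndvi: np.ndarray, band: str) -> np.ndarray:
    """Band reflectance fraction as an exact function of NDVI."""
    if band == "red":
        return TOTAL_RED_NIR * (1.0 - ndvi) / 2.0
    if band == "nir":
        return TOTAL_RED_NIR * (1.0 + ndvi) / 2.0
    if band == "green":
        return 0.08 + 0.10 * ndvi
    if band == "red_edge":
        return 0.15 + 0.15 * ndvi
    if band == "blue":
        return 0.06 + 0.02 * ndvi
    raise ValueError(f"unknown band {band!r}")


def _paint_flat_square(grids, ndvi, c0, r0, size_px, reflectance_pct):
    """Spectrally flat target: same reflectance in every band, NDVI 0."""
    c1, r1 = c0 + size_px, r0 + size_px
    for g in grids.values():
        g[r0:r1, c0:c1] = reflectance_pct / 100.0
    ndvi[r0:r1, c0:c1] = 0.0
    return (c0, r0, c1, r1)


def render_ortho(
    plants: pd.DataFrame,
    layout: TrialLayout,
    bands=("blue", "green", "red", "red_edge", "nir"),
    dn_gain: float | None = None,
    dn_offset: float = 0.0,
    noise_sd: float = 0.0,
    max_pixels: int = 120_000_000,
    seed: int | None = None,
):
    """Render the multiband ortho-mosaic plus NDVI ground truth.

    Returns ``(raster, ndvi_truth, panels, gcps)``.  With ``dn_gain`` set
    the bands are digital numbers ``DN = (reflectance_pct - dn_offset) /
    dn_gain`` (uint16), i.e. the exact inverse of the empirical line the
    calibration stage fits; otherwise float32 reflectance fractions.
    Gaussian noise (sd in reflectance-fraction units) is added per band
    when ``noise_sd > 0``.  Panels and GCP markers render spectrally flat
    (NDVI 0) in the soil margins outside the trial area.
    """
    h, w = layout.raster_height_px, layout.raster_width_px
    if h * w * len(bands) > max_pixels:
        raise LayoutError(
            f"render of {h}x{w}x{len(bands)} exceeds max_pixels={max_pixels}"
        )
    rng = np.random.default_rng(
        layout.rng_seed + 1 if seed is None else seed
    )
    ndvi = _ndvi_field(plants, layout, rng)
    grids = {b: _reflectance_from_ndvi(ndvi, b) for b in bands}

    gsd = layout.gsd
    fx0, fy0, fx1, fy1 = layout.field_bbox()
    panel_px = max(2, int(round(PANEL_SIZE_M / gsd)))
    marker_px = max(2, int(round(GCP_MARKER_SIZE_M / gsd)))

    # reflectance panels: stacked in the left margin
    panels = []
    pc0 = max(0, int(round((layout.margin / 2 - PANEL_SIZE_M / 2) / gsd)))
    pr0 = int(round(fy0 / gsd))
    for i, pct in enumerate(PANEL_REFLECTANCES_PCT):
        box = _paint_flat_square(
            grids, ndvi, pc0, pr0 + i * 2 * panel_px, panel_px, pct
        )
        panels.append(PanelSpec(reflectance_pct=pct, box_px=box))

    # 9 GCPs: 4 field-bbox corners, 4 edge midpoints, 1 offset corner.
    # The recorded coordinate is the marker's field-facing corner/edge
    # point; markers themselves sit just outside the trial area.
    corner_pts = [(fx0, fy0), (fx1, fy0), (fx1, fy1), (fx0, fy1)]
    mid_pts = [
        ((fx0 + fx1) / 2, fy0), (fx1, (fy0 + fy1) / 2),
        ((fx0 + fx1) / 2, fy1), (fx0, (fy0 + fy1) / 2),
    ]
    extra_pts = [(fx0 - 1.0, fy0 - 1.0)]
    gcp_rows = []
    t = layout.transform
    m = GCP_MARKER_SIZE_M
    for i, (gx, gy) in enumerate(corner_pts + mid_pts + extra_pts):
        role = "corner" if i < 4 else "edge"
        # marker square always painted on the margin side of its reference
        # point so it never covers trial plants
        if gx <= fx0:
            mx = gx - m
        elif gx >= fx1:
            mx = gx
        else:
            mx = gx - m / 2
        if gy <= fy0:
            my = gy - m
        elif gy >= fy1:
            my = gy
        else:
            my = gy - m / 2
        _paint_flat_square(
            grids, ndvi, int(round(mx / gsd)), int(round(my / gsd)),
            marker_px, 45.0,
        )
        col, row = gx / gsd, gy / gsd
        wxy = t.forward(col, row)
        gcp_rows.append(
            dict(
                id=f"gcp-{i + 1}", role=role,
                world_x=float(wxy[0]), world_y=float(wxy[1]),
                pixel_col=col, pixel_row=row,
            )
        )
    gcps = pd.DataFrame(gcp_rows)

    band_list = list(bands)
    if dn_gain is not None:
        data = np.empty((len(band_list), h, w), dtype=np.uint16)
        for i, b in enumerate(band_list):
            refl_pct = grids[b] * 100.0
            if noise_sd > 0:
                refl_pct = refl_pct + rng.normal(0, noise_sd * 100, (h, w))
            data[i] = np.clip(
                np.rint((refl_pct - dn_offset) / dn_gain), 0, 65535
            ).astype(np.uint16)
        nodata = 65535.0
    else:
        data = np.empty((len(band_list), h, w), dtype=np.float32)
        for i, b in enumerate(band_list):
            g = grids[b]
            if noise_sd > 0:
                g = g + rng.normal(0, noise_sd, (h, w))
            data[i] = g.astype(np.float32)
        nodata = -9999.0

    raster = MultibandRaster(
        data=data, transform=t, crs=layout.crs,
        band_labels=tuple(band_list),
        wavelengths_nm=tuple(BAND_WAVELENGTHS[b] for b in band_list),
        nodata=nodata,
    )
    ndvi_truth = MultibandRaster(
        data=ndvi.astype(np.float32)[None], transform=t, crs=layout.crs,
        band_labels=("ndvi",), nodata=-9999.0,
    )
    return raster, ndvi_truth, panels, gcps


def default_path(layout: TrialLayout):
    """Serpentine pass along every plant-row line (image-frame metres)."""
    waypoints = []
    fy0 = layout.margin - 0.5
    fy1 = layout.margin + layout.field_height + 0.5
    for gr in range(layout.rows_per_block):
        cx = layout.margin + (gr + 0.5) * layout.row_spacing
        if gr % 2 == 0:
            waypoints.append(((cx, fy0), (cx, fy1)))
        else:
            waypoints.append(((cx, fy1), (cx, fy0)))
    return waypoints


def simulate_height_track(
    plants: pd.DataFrame,
    layout: TrialLayout,
    rig: SensorRig = SensorRig(),
    path=None,
    seed: int | None = None,
    start_time: str = "2018-06-14T09:00:00",
) -> pd.DataFrame:
    """Drive the sensor rig over the field and log ultrasonic ranges.

    Each record is (timestamp ISO-8601, lat, lon, sensor_index, range_m)
    where lat/lon is the RTK antenna fix.  A sensor directly over a plant
    (horizontal distance to the nearest plant centre within its radius)
    reads ``mount_height - true_height``; over bare ground it reads the
    mount height; Gaussian range noise is added if configured.
    """
    rng = np.random.default_rng(
        layout.rng_seed + 2 if seed is None else seed
    )
    if path is None:
        path = default_path(layout)
    fx0, fy0, fx1, fy1 = layout.field_bbox()
    guard = 2.0 + max(abs(o) for o in rig.lateral_offsets)
    inside = False
    for (x0, y0), (x1, y1) in path:
        if (
            min(x0, x1) < fx1 + guard and max(x0, x1) > fx0 - guard
            and min(y0, y1) < fy1 + guard and max(y0, y1) > fy0 - guard
        ):
            inside = True
    if not inside:
        import warnings

        warnings.warn("vehicle path never enters the field; empty track")
        return pd.DataFrame(
            columns=["timestamp", "lat", "lon", "sensor_index", "range_m"]
        )

    # grid lookup of plant centres for nearest-plant queries
    cell = max(layout.plant_spacing, 2 * layout.plant_radius)
    grid: dict[tuple, list[int]] = {}
    px = plants["x"].to_numpy()
    py = plants["y"].to_numpy()
    pr = plants["radius"].to_numpy()
    ph = plants["true_height_cm"].to_numpy()
    for i, (x, y) in enumerate(zip(px, py)):
        grid.setdefault((int(x // cell), int(y // cell)), []).append(i)

    def range_at(x, y):
        gx, gy = int(x // cell), int(y // cell)
        best_d2, best = None, None
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for i in grid.get((gx + dx, gy + dy), ()):
                    d2 = (px[i] - x) ** 2 + (py[i] - y) ** 2
                    if best_d2 is None or d2 < best_d2:
                        best_d2, best = d2, i
        if best is not None and best_d2 <= pr[best] ** 2:
            return rig.mount_height - ph[best] / 100.0
        return rig.mount_height

    t = layout.transform
    step = rig.speed / rig.sample_rate
    t0 = pd.Timestamp(start_time)
    records = []
    elapsed = 0.0
    for (x0, y0), (x1, y1) in path:
        seg = math.hypot(x1 - x0, y1 - y0)
        if seg == 0:
            continue
        ux, uy = (x1 - x0) / seg, (y1 - y0) / seg
        rx, ry = -uy, ux  # right-hand perpendicular in image frame (y down)
        n_steps = int(seg / step) + 1
        for si in range(n_steps):
            ax, ay = x0 + ux * si * step, y0 + uy * si * step
            wx, wy = t.forward(ax / layout.gsd, ay / layout.gsd)
            lat, lon = utm.utm_to_latlon(
                wx, wy, layout.utm_zone, layout.utm_south
            )
            ts = (t0 + pd.Timedelta(seconds=elapsed)).isoformat()
            for s, off in enumerate(rig.lateral_offsets):
                sx, sy = ax + off * rx, ay + off * ry
                rg = range_at(sx, sy)
                if rig.range_noise_sd > 0:
                    rg += rng.normal(0, rig.range_noise_sd)
                records.append(
                    dict(
                        timestamp=ts, lat=float(lat), lon=float(lon),
                        sensor_index=s, range_m=float(rg),
                    )
                )
            elapsed += 1.0 / rig.sample_rate
    return pd.DataFrame(records)


def simulate_harvest(
    plants: pd.DataFrame,
    season: str,
    model: SeasonModel | None = None,
    noise_sd: float = 0.0,
    truncate_negative: bool = False,
    seed: int | None = None,
    predictor_exponent: float = 2.0,
):
    """Simulate destructive harvests from the seasonal biomass model.

    Per-plant measured grams are the seasonal equation evaluated at the
    plant's true predictor plus Gaussian noise; plot kilograms are the sum
    of the plot's plants / 1000.  Negative simulated weights are kept by
    default (the model is linear and can go negative); set
    ``truncate_negative`` to floor them at zero — the choice is recorded
    on the returned frames.  Returns ``(per_plant, per_plot)``.
    """
    model = model or SeasonModel()
    rng = np.random.default_rng(seed if seed is not None else 3)
    predictor = (
        plants["true_ndvi"].to_numpy() ** predictor_exponent
        * plants["true_height_cm"].to_numpy()
    )
    grams = predict_dmy(predictor, season, model)
    if noise_sd > 0:
        grams = grams + rng.normal(0, noise_sd, size=len(grams))
    if truncate_negative:
        grams = np.maximum(grams, 0.0)
    per_plant = pd.DataFrame(
        dict(
            plant_id=plants["plant_id"], plot_id=plants["plot_id"],
            entry=plants["entry"], season=season,
            true_predictor=predictor, measured_g=grams,
        )
    )
    per_plot = (
        per_plant.groupby(["plot_id", "entry"], as_index=False)["measured_g"]
        .sum()
        .rename(columns={"measured_g": "measured_kg"})
    )
    per_plot["measured_kg"] /= 1000.0
    per_plot["season"] = season
    for frame in (per_plant, per_plot):
        frame.attrs["truncate_negative"] = truncate_negative
        frame.attrs["season_model_mode"] = model.mode
    return per_plant, per_plot
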