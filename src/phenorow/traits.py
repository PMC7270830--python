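"""Per-plant trait extraction: zonal NDVI statistics and ultrasonic height.

NDVI statistics aggregate the pixels whose centres fall inside each plant
polygon (half-open rectangles, so adjacent plants never share a pixel).
Heights come from a ground vehicle: an RTK antenna track in lat/lon is
projected to UTM, each ultrasonic sensor's position is offset laterally
from the antenna using the heading between consecutive fixes, and every
range sample falling inside a plant polygon contributes
``height_cm = (mount_height - range) * 100`` to that plant; the per-plant
statistic is the median (robust to soil echoes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import utm

__all__ = [
    "HeightSample",
    "TraitRecord",
    "extract_ndvi_stats",
    "project_track",
    "match_heights",
    "compute_predictor",
    "build_trait_table",
    "PREDICTOR_DEFINITION",
]

# Active definition of the combined NDVI/height biomass predictor.  The
# exponent and height units are configurable because the canonical formula
# is calibrated elsewhere; the definition string is carried into every
# output file so downstream users know exactly what was computed.
PREDICTOR_DEFINITION = "ndvi**2 * height_cm"


@dataclass(frozen=True)
class HeightSample:
    timestamp: str
    x: float
    y: float
    sensor_index: int
    range_m: float

    @property
    def height_cm(self) -> float:
        return self.range_m  # placeholder; height needs the rig mount height


@dataclass
class TraitRecord:
    plant_id: str
    ndvi_mean: float = float("nan")
    ndvi_median: float = float("nan")
    ndvi_max: float = float("nan")
    n_pixels: int = 0
    height_cm: float = float("nan")
    n_height_samples: int = 0
    predictor: float = float("nan")
    flags: str = ""


def extract_ndvi_stats(ndvi, polygons, nodata=-9999.0) -> pd.DataFrame:
    """Zonal NDVI statistics per plant polygon.

    Polygons are half-open pixel rectangles; a pixel belongs to the
    polygon iff its centre does, so adjacent plant polygons partition
    their row box without double counting.  Nodata pixels are excluded;
    a polygon with no valid pixel is flagged ``empty``.
    """
    ndvi = np.asarray(ndvi, dtype=np.float64)
    rows = []
    for p in polygons:
        vals = ndvi[p.y0:p.y1, p.x0:p.x1].ravel()
        vals = vals[vals != nodata]
        if vals.size == 0:
            rows.append(
                dict(plant_id=p.plant_id, ndvi_mean=np.nan, ndvi_median=np.nan,
                     ndvi_max=np.nan, n_pixels=0, flags="empty")
            )
        else:
            rows.append(
                dict(plant_id=p.plant_id, ndvi_mean=float(vals.mean()),
                     ndvi_median=float(np.median(vals)),
                     ndvi_max=float(vals.max()), n_pixels=int(vals.size),
                     flags="")
            )
    return pd.DataFrame(rows)


def project_track(track: pd.DataFrame, lateral_offsets, zone=None) -> pd.DataFrame:
    """Project an RTK track to UTM and position each sensor.

    ``track`` columns: timestamp, lat, lon, sensor_index, range_m.
    ``lateral_offsets[i]`` is sensor i's signed offset (m) to the right of
    the direction of travel.  Headings come from consecutive distinct
    fixes; stationary duplicates inherit the last moving heading.
    Returns the track with added ``x``/``y`` (sensor UTM position) columns.
    """
    if track.empty:
        raise ValueError("empty track")
    e, n, zone, south = utm.latlon_to_utm(
        track["lat"].to_numpy(), track["lon"].to_numpy(), zone=zone
    )
    e = np.atleast_1d(e)
    n = np.atleast_1d(n)
    # heading unit vector per fix, carried over stationary duplicates
    dx = np.diff(e)
    dy = np.diff(n)
    hx = np.empty(len(e))
    hy = np.empty(len(e))
    last = (0.0, 1.0)  # default: due north
    for i in range(len(e)):
        if i < len(dx) and (dx[i] != 0 or dy[i] != 0):
            norm = math.hypot(dx[i], dy[i])
            last = (dx[i] / norm, dy[i] / norm)
        hx[i], hy[i] = last
    # right-hand perpendicular of the heading
    px, py = hy, -hx
    off = np.asarray(
        [lateral_offsets[int(s)] for s in track["sensor_index"]], dtype=float
    )
    out = track.copy()
    out["x"] = e + off * px
    out["y"] = n + off * py
    out.attrs["utm_zone"] = zone
    out.attrs["utm_south"] = south
    return out


def match_heights(
    samples: pd.DataFrame,
    polygons,
    world_to_pixel,
    mount_height: float = 0.6,
    stat: str = "median",
    ground_cutoff_cm: float = 2.0,
) -> pd.DataFrame:
    """Assign projected height samples to plant polygons.

    ``world_to_pixel(x, y)`` maps sensor UTM coordinates into the rectified
    pixel frame the polygons live in.  Heights below zero (range beyond
    the mount height) are floored at 0 and counted.  Samples at or below
    ``ground_cutoff_cm`` are ground echoes — the sonar footprint missing
    the crown and ranging the soil — and are dropped (with a count) before
    aggregation, otherwise they drag every plant's median toward zero.
    Returns a DataFrame (plant_id, height_cm, n_height_samples) plus drop
    counts in ``attrs``.
    """
    if samples.empty:
        raise ValueError("no height samples supplied")
    cols, rows_ = world_to_pixel(
        samples["x"].to_numpy(), samples["y"].to_numpy()
    )
    heights = (mount_height - samples["range_m"].to_numpy()) * 100.0
    n_floored = int(np.sum(heights < 0))
    heights = np.maximum(heights, 0.0)
    keep = heights > ground_cutoff_cm
    n_ground = int(np.sum(~keep))
    per_plant: dict[str, list[float]] = {}
    n_unassigned = 0
    finder = getattr(polygons, "find", None)
    for c, r, h, ok in zip(
        np.atleast_1d(cols), np.atleast_1d(rows_), heights, keep
    ):
        if not ok:
            continue
        if finder is not None:
            hit = finder(c, r)
        else:
            hit = None
            for p in polygons:
                if p.x0 <= c < p.x1 and p.y0 <= r < p.y1:
                    hit = p
                    break
        if hit is None:
            n_unassigned += 1
            continue
        per_plant.setdefault(hit.plant_id, []).append(float(h))
    if not per_plant:
        raise ValueError("no height samples fell inside the field polygons")
    agg = np.median if stat == "median" else np.mean
    out = pd.DataFrame(
        [
            dict(plant_id=pid, height_cm=float(agg(v)), n_height_samples=len(v))
            for pid, v in per_plant.items()
        ]
    )
    out.attrs["n_unassigned"] = n_unassigned
    out.attrs["n_floored"] = n_floored
    out.attrs["n_ground_echo"] = n_ground
    return out


def compute_predictor(ndvi_stat, height_cm, exponent: float = 2.0):
    """Combined NDVI/height biomass predictor (default ``ndvi**2 * height``).

    Returns NaN when either trait is missing so the record stays flagged
    rather than silently predicted.
    """
    ndvi_stat = np.asarray(ndvi_stat, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    return ndvi_stat**exponent * height_cm


def build_trait_table(
    ndvi_stats: pd.DataFrame,
    heights: pd.DataFrame | None,
    exponent: float = 2.0,
) -> pd.DataFrame:
    """Join NDVI statistics and heights and add the biomass predictor."""
    if heights is None or heights.empty:
        out = ndvi_stats.copy()
        out["height_cm"] = np.nan
        out["n_height_samples"] = 0
    else:
        out = ndvi_stats.merge(heights, on="plant_id", how="left")
        out["n_height_samples"] = (
            out["n_height_samples"].fillna(0).astype(int)
        )
    out["ndvisq_ph"] = compute_predictor(
        out["ndvi_mean"], out["height_cm"], exponent=exponent
    )
    missing = out["ndvisq_ph"].isna() & (out["flags"] == "")
    out.loc[missing, "flags"] = "no_height"
    out.attrs["predictor_definition"] = PREDICTOR_DEFINITION
    return out
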