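"""Empirical-line radiometric calibration and NDVI computation.

Calibration targets of known reflectance (by default 6, 11, 22 and 33 %)
are imaged alongside the trial; an ordinary least-squares line
``reflectance_pct = gain * DN + offset`` is fitted per band and applied to
convert digital numbers to reflectance fractions.  NDVI is then
``(NIR - Red) / (NIR + Red)``.

The regression is fitted with reflectance as the response so application
is a direct affine map of the DN grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geo import MultibandRaster, Affine, DEFAULT_NODATA

__all__ = [
    "PanelObservation",
    "BandCalibration",
    "CalibrationError",
    "panel_mean_dn",
    "fit_calibration",
    "apply_calibration",
    "compute_ndvi",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PanelObservation:
    """Mean digital number over one reflectance panel in one band."""

    band: str
    reflectance_pct: float
    mean_dn: float

    def __post_init__(self):
        if not 0 < self.reflectance_pct < 100:
            raise CalibrationError(
                f"panel reflectance must be in (0, 100) %, got "
                f"{self.reflectance_pct}"
            )


@dataclass(frozen=True)
class BandCalibration:
    """Fitted empirical line for one band: reflectance_pct = gain*DN + offset."""

    band: str
    gain: float
    offset: float
    r_squared: float
    n_panels: int


def panel_mean_dn(band_grid, box, trim=0.0):
    """Mean DN over a half-open pixel box (col0, row0, col1, row1).

    ``trim`` optionally discards that fraction from each tail before
    averaging, which guards panel means against edge pixels.
    """
    c0, r0, c1, r1 = box
    vals = np.asarray(band_grid)[r0:r1, c0:c1].ravel()
    if vals.size == 0:
        raise CalibrationError("empty panel region")
    if trim > 0:
        vals = np.sort(vals)
        k = int(len(vals) * trim)
        if len(vals) - 2 * k >= 1:
            vals = vals[k: len(vals) - k]
    return float(np.mean(vals))


def fit_calibration(observations) -> dict:
    """Fit per-band empirical lines from panel observations.

    Returns ``{band: BandCalibration}``.  At least two panels with
    distinct DN are required per band.
    """
    by_band: dict[str, list[PanelObservation]] = {}
    for obs in observations:
        by_band.setdefault(obs.band, []).append(obs)
    out = {}
    for band, obs_list in by_band.items():
        dn = np.asarray([o.mean_dn for o in obs_list], dtype=float)
        refl = np.asarray([o.reflectance_pct for o in obs_list], dtype=float)
        if len(dn) < 2 or np.ptp(dn) == 0:
            raise CalibrationError(
                f"band {band!r}: need >= 2 panels with distinct DN to fit a "
                "line"
            )
        gain, offset = np.polyfit(dn, refl, 1)
        fitted = gain * dn + offset
        ss_res = float(np.sum((refl - fitted) ** 2))
        ss_tot = float(np.sum((refl - refl.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        out[band] = BandCalibration(
            band=band, gain=float(gain), offset=float(offset),
            r_squared=r2, n_panels=len(dn),
        )
    return out


def apply_calibration(raster: MultibandRaster, calibrations: dict):
    """Convert DN bands to reflectance fractions in [0, 1].

    Out-of-range values are clipped and counted; nodata pixels propagate.
    Returns ``(reflectance MultibandRaster (float32), clip_counts dict)``.
    """
    out = np.empty(raster.data.shape, dtype=np.float32)
    clip_counts = {}
    for i, band in enumerate(raster.band_labels):
        if band not in calibrations:
            raise CalibrationError(f"no calibration for band {band!r}")
        cal = calibrations[band]
        dn = raster.data[i].astype(np.float64)
        refl = (cal.gain * dn + cal.offset) / 100.0
        valid = raster.mask_valid(i)
        n_clip = int(np.sum(valid & ((refl < 0) | (refl > 1))))
        refl = np.clip(refl, 0.0, 1.0)
        refl[~valid] = DEFAULT_NODATA
        out[i] = refl
        clip_counts[band] = n_clip
    calibrated = MultibandRaster(
        data=out,
        transform=raster.transform,
        crs=raster.crs,
        band_labels=raster.band_labels,
        wavelengths_nm=raster.wavelengths_nm,
        nodata=DEFAULT_NODATA,
    )
    return calibrated, clip_counts


def compute_ndvi(red, nir, nodata=DEFAULT_NODATA):
    """NDVI = (NIR - Red) / (NIR + Red) on reflectance grids.

    Inputs may be 2-D arrays or (raster, labels are looked up by caller).
    Pixels where the denominator is zero, or where either input is nodata,
    become ``nodata`` in the output (float32).
    """
    red = np.asarray(red, dtype=np.float64)
    nir = np.asarray(nir, dtype=np.float64)
    if red.shape != nir.shape:
        raise ValueError(
            f"red/nir shape mismatch: {red.shape} vs {nir.shape}"
        )
    invalid = (red == nodata) | (nir == nodata)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir - red) / denom
    ndvi[invalid | (denom == 0)] = nodata
    return ndvi.astype(np.float32)


def ndvi_raster(raster: MultibandRaster) -> MultibandRaster:
    """Compute a single-band NDVI raster from a reflectance raster."""
    ndvi = compute_ndvi(
        raster.band("red"), raster.band("nir"), nodata=raster.nodata
    )
    return MultibandRaster(
        data=ndvi[None],
        transform=raster.transform,
        crs=raster.crs,
        band_labels=("ndvi",),
        nodata=DEFAULT_NODATA,
    )
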