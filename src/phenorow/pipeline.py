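"""End-to-end orchestration: files in, traits and predictions out.

Stages run in the workflow order — calibrate -> NDVI -> rectify ->
blocks/rows -> box growing -> consensus -> plant centres -> plant
polygons -> NDVI statistics -> heights -> biomass prediction -> plot
aggregation -> validation — with every stage reading and writing plain
files in the run directory so stages are independently testable and a
re-run with the same config is bit-identical for the deterministic
stages.  A JSON manifest records parameters, seeds and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import detection, segmentation, traits, utm
from .biomass import SEASONS, SeasonModel, aggregate_plot, predict_dmy, validate
from .calibration import (
    PanelObservation,
    apply_calibration,
    compute_ndvi,
    fit_calibration,
    panel_mean_dn,
)
from .geo import (
    GroundControlPoint,
    MultibandRaster,
    PerspectiveMapping,
    perspective_transform,
    read_raster,
    write_raster,
)
from .synthetic import (
    SensorRig,
    TrialLayout,
    generate_layout,
    render_ortho,
    simulate_harvest,
    simulate_height_track,
)

log = logging.getLogger("phenorow")

__all__ = ["RunConfig", "simulate", "run_pipeline", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a pipeline run needs; mirrors the CLI flags."""

    out_dir: str = "phenorow_run"
    raster: str | None = None          # DN ortho-mosaic GeoTIFF
    ndvi_raster: str | None = None     # or a precomputed NDVI GeoTIFF
    gcps: str | None = None
    panels: str | None = None
    track: str | None = None
    edits: str | None = None
    harvest: str | None = None
    season: str = "winter2018"
    season_model_mode: str = "reconstructed"
    # trial layout (drives segmentation parameters and plant IDs)
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
    plant_radius: float = 0.12
    # template matching
    template_width: int = 20
    template_height: int = 20
    template_context: int = 4
    template_threshold: float = 0.6
    template_tolerance: int = 3
    n_template_samples: int = 35
    # box growing
    grow_variant: str = "prose"
    background_t: float | None = None
    # rig
    mount_height: float = 0.6
    seed: int = 0
    bands: tuple = ("red", "nir")
    noise_sd: float = 0.0
    track_noise_sd: float = 0.0
    harvest_noise_sd: float = 0.0
    dn_gain: float = 0.1
    dn_offset: float = 0.0

    def layout(self) -> TrialLayout:
        return TrialLayout(
            n_entries=self.n_entries, n_reps=self.n_reps,
            rows_per_plot=self.rows_per_plot,
            plants_per_row=self.plants_per_row,
            plant_spacing=self.plant_spacing, row_spacing=self.row_spacing,
            plot_length=self.plot_length, plot_width=self.plot_width,
            n_blocks=self.n_blocks, gsd=self.gsd,
            plant_radius=self.plant_radius, rng_seed=self.seed,
        )

    def segmentation_params(self) -> segmentation.SegmentationParams:
        return segmentation.SegmentationParams(
            row_length_px=int(round(self.plot_length / self.gsd)),
            plant_width_px=int(round(2 * self.plant_radius / self.gsd)),
            background_t=self.background_t,
            grow_variant=self.grow_variant,
        )


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bands" in raw:
        raw["bands"] = tuple(raw["bands"])
    cfg = RunConfig(**raw)
    if cfg.season not in SEASONS:
        raise ValueError(
            f"invalid season {cfg.season!r}; valid: {list(SEASONS)}"
        )
    return cfg


# ---------------------------------------------------------------------------
# synthetic dataset on disk


def simulate(config: RunConfig) -> dict:
    """Write a full synthetic dataset into the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout()
    plants, rows, plots = generate_layout(layout)
    raster, ndvi_truth, panels, gcps = render_ortho(
        plants, layout, bands=config.bands,
        dn_gain=config.dn_gain, dn_offset=config.dn_offset,
        noise_sd=config.noise_sd, seed=config.seed + 1,
    )
    write_raster(raster, out / "ortho.tif")
    write_raster(ndvi_truth, out / "ndvi_truth.tif")
    plants.to_csv(out / "plants.csv", index=False)
    rows.to_csv(out / "rows.csv", index=False)
    plots.to_csv(out / "plots.csv", index=False)
    gcps.to_csv(out / "gcps.csv", index=False)
    pd.DataFrame(
        [
            dict(
                reflectance_pct=p.reflectance_pct,
                col0=p.box_px[0], row0=p.box_px[1],
                col1=p.box_px[2], row1=p.box_px[3],
            )
            for p in panels
        ]
    ).to_csv(out / "panels.csv", index=False)
    rig = SensorRig(
        mount_height=config.mount_height,
        range_noise_sd=config.track_noise_sd,
    )
    track = simulate_height_track(
        plants, layout, rig=rig, seed=config.seed + 2
    )
    track.to_csv(out / "track.csv", index=False)
    per_plant, per_plot = simulate_harvest(
        plants, config.season,
        model=SeasonModel(mode=config.season_model_mode),
        noise_sd=config.harvest_noise_sd, seed=config.seed + 3,
    )
    per_plant.to_csv(out / "harvest_plants.csv", index=False)
    per_plot.to_csv(out / "harvest_plots.csv", index=False)
    counts = dict(
        plots=len(plots), rows=len(rows), plants=len(plants),
        gcps=len(gcps), panels=len(panels), track_records=len(track),
    )
    (out / "simulate_manifest.json").write_text(
        json.dumps(dict(seed=config.seed, counts=counts), indent=2)
    )
    return counts


# ---------------------------------------------------------------------------
# pipeline stages


def _geojson_feature(coords_world, props):
    ring = [[float(x), float(y)] for x, y in coords_world]
    ring.append(ring[0])
    return dict(
        type="Feature",
        geometry=dict(type="Polygon", coordinates=[ring]),
        properties=props,
    )


def _rect_to_world(mapping: PerspectiveMapping, x0, y0, x1, y1):
    corners = np.asarray(
        [[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float
    )
    return mapping.rectified_to_world(corners)


def boxes_to_geojson(boxes, mapping, crs):
    feats = []
    for b in boxes:
        props = dict(
            id=b.id, block=b.block_index + 1, row=b.row_index + 1,
            x0=b.x0, y0=b.y0, x1=b.x1, y1=b.y1, area_px=b.area,
            grown_top=b.grown_top, grown_bottom=b.grown_bottom,
        )
        feats.append(
            _geojson_feature(
                _rect_to_world(mapping, b.x0, b.y0, b.x1, b.y1), props
            )
        )
    return dict(type="FeatureCollection", crs_name=crs, features=feats)


def polygons_to_geojson(polys, mapping, crs):
    feats = []
    for p in polys:
        props = dict(
            plant_id=p.plant_id, box_id=p.box_id, position=p.position,
            x0=p.x0, y0=p.y0, x1=p.x1, y1=p.y1, area_px=p.area,
            center_col=p.center_col, center_row=p.center_row,
        )
        feats.append(
            _geojson_feature(
                _rect_to_world(mapping, p.x0, p.y0, p.x1, p.y1), props
            )
        )
    return dict(type="FeatureCollection", crs_name=crs, features=feats)


def _read_gcps(path) -> list[GroundControlPoint]:
    df = pd.read_csv(path)
    return [
        GroundControlPoint(
            id=str(r.id), world_x=float(r.world_x), world_y=float(r.world_y),
            pixel_col=float(r.pixel_col), pixel_row=float(r.pixel_row),
        )
        for r in df.itertuples()
    ], df


def stage_calibrate(config: RunConfig, out: Path) -> dict:
    """Fit the empirical line on the panels and write the NDVI raster."""
    if config.ndvi_raster:
        ndvi_r = read_raster(config.ndvi_raster)
        write_raster(ndvi_r, out / "ndvi.tif")
        return dict(calibrated=False, bands=list(ndvi_r.band_labels))
    raster = read_raster(config.raster)
    panels = pd.read_csv(config.panels)
    obs = []
    for band in raster.band_labels:
        grid = raster.band(band)
        for r in panels.itertuples():
            obs.append(
                PanelObservation(
                    band=band, reflectance_pct=float(r.reflectance_pct),
                    mean_dn=panel_mean_dn(
                        grid, (int(r.col0), int(r.row0), int(r.col1), int(r.row1))
                    ),
                )
            )
    cals = fit_calibration(obs)
    pd.DataFrame(
        [asdict(c) for c in cals.values()]
    ).to_csv(out / "calibration.csv", index=False)
    refl, clip_counts = apply_calibration(raster, cals)
    for band, n in clip_counts.items():
        if n:
            log.warning("band %s: %d reflectance values clipped", band, n)
    ndvi = compute_ndvi(
        refl.band("red"), refl.band("nir"), nodata=refl.nodata
    )
    ndvi_r = MultibandRaster(
        data=ndvi[None], transform=raster.transform, crs=raster.crs,
        band_labels=("ndvi",), nodata=-9999.0,
    )
    write_raster(ndvi_r, out / "ndvi.tif")
    return dict(
        calibrated=True, clip_counts=clip_counts,
        calibration={b: dict(gain=c.gain, offset=c.offset, r2=c.r_squared)
                     for b, c in cals.items()},
    )


def stage_segment(config: RunConfig, out: Path) -> dict:
    """Rectify on the corner GCPs, find blocks/rows, grow the boxes."""
    ndvi_r = read_raster(out / "ndvi.tif")
    gcps, gcp_df = _read_gcps(config.gcps)
    corners = [g for g in gcps if "corner" in str(
        gcp_df.set_index("id").loc[g.id, "role"]
    )] if "role" in gcp_df.columns else gcps[:4]
    if len(corners) != 4:
        raise StageError("segment", f"need 4 corner GCPs, got {len(corners)}")
    rect, mapping = perspective_transform(ndvi_r, corners)
    write_raster(rect, out / "ndvi_rectified.tif")
    np.save(out / "homography.npy", mapping.homography)

    img = segmentation.shifted_ndvi(rect.data[0], nodata=rect.nodata)
    params = config.segmentation_params()
    bands = segmentation.detect_blocks(img, params, n_expected=config.n_blocks)
    rows_per_band = [
        segmentation.detect_rows(img, b, params) for b in bands
    ]
    boxes = segmentation.initial_row_boxes(bands, rows_per_band)
    grown, links, t_used = segmentation.link_and_grow(
        boxes, img, t=params.background_t, variant=params.grow_variant
    )
    label, consensus, report = segmentation.select_consensus(
        [("run", grown)]
    )
    (out / "row_polygons.geojson").write_text(
        json.dumps(boxes_to_geojson(consensus, mapping, ndvi_r.crs))
    )
    pd.DataFrame(
        report, columns=["date", "n_polygons", "area_variance"]
    ).to_csv(out / "polygon_variance.csv", index=False)
    return dict(
        n_blocks=len(bands), n_rows=len(consensus),
        rows_per_block=[len(r) for r in rows_per_band],
        background_t=t_used, n_links=len(links),
    )


def _load_boxes(out: Path):
    gj = json.loads((out / "row_polygons.geojson").read_text())
    boxes = []
    for f in gj["features"]:
        p = f["properties"]
        boxes.append(
            segmentation.RowBox(
                block_index=p["block"] - 1, row_index=p["row"] - 1,
                x0=p["x0"], y0=p["y0"], x1=p["x1"], y1=p["y1"],
                grown_top=p.get("grown_top", 0),
                grown_bottom=p.get("grown_bottom", 0),
            )
        )
    return boxes


def auto_sample_centers(img, boxes, n, half):
    """Pick bright, well-separated in-box local maxima as template samples.

    Stands in for the operator hand-picking representative plants from a
    small test region: strict local maxima of the vegetation index inside
    the first few row boxes, strongest first, at least a window apart,
    windows fully inside the image.
    """
    region_boxes = [
        b for b in boxes[:12] if b.block_index == boxes[0].block_index
    ]
    rx0 = min(b.x0 for b in region_boxes)
    rx1 = max(b.x1 for b in region_boxes)
    ry0 = min(b.y0 for b in region_boxes)
    ry1 = max(b.y1 for b in region_boxes)
    sub = img[ry0:ry1, rx0:rx1]
    maxf = ndimage.maximum_filter(sub, size=2 * half + 1)
    cand = np.argwhere((sub >= maxf) & (sub > np.median(sub)))
    vals = sub[cand[:, 0], cand[:, 1]]
    order = np.argsort(vals)[::-1]
    picked = []
    for idx in order:
        r, c = int(cand[idx, 0]) + ry0, int(cand[idx, 1]) + rx0
        if not (half <= r < img.shape[0] - half
                and half <= c < img.shape[1] - half):
            continue
        if not any(b.contains(c, r) for b in region_boxes):
            continue
        if any((pr - r) ** 2 + (pc - c) ** 2 < (2 * half) ** 2
               for pc, pr in picked):
            continue
        picked.append((c, r))
        if len(picked) >= n:
            break
    if len(picked) < 2:
        raise StageError("detect", "could not find template sample windows")
    return picked


def stage_detect(config: RunConfig, out: Path) -> dict:
    """Template matching, QC filtering and per-plant polygon splitting."""
    rect = read_raster(out / "ndvi_rectified.tif")
    img = segmentation.shifted_ndvi(rect.data[0], nodata=rect.nodata)
    boxes = _load_boxes(out)
    half = (config.template_width + 2 * config.template_context) // 2
    samples = auto_sample_centers(
        img, boxes, config.n_template_samples, half
    )
    model = detection.build_template(
        img, samples,
        width=config.template_width, height=config.template_height,
        context=config.template_context,
        threshold=config.template_threshold,
        tolerance_px=config.template_tolerance,
    )
    candidates = detection.match_template(img, model)
    edits = []
    if config.edits:
        edf = pd.read_csv(config.edits)
        edits = list(edf[["action", "col", "row"]].itertuples(index=False))
    index = detection.RectIndex(boxes, img.shape)
    kept, n_outside = detection.filter_and_qc(
        candidates, index, edits=edits, image_shape=img.shape
    )
    polys, empty_boxes = detection.split_all(boxes, kept)
    for bid in empty_boxes:
        log.warning("row box %s contains no plant centres", bid)

    mapping = PerspectiveMapping(
        homography=np.load(out / "homography.npy"),
        source_transform=read_raster(out / "ndvi.tif").transform,
        crs=rect.crs,
    )
    (out / "plant_polygons.geojson").write_text(
        json.dumps(polygons_to_geojson(polys, mapping, rect.crs))
    )
    centers = pd.DataFrame(
        [
            dict(col=c.col, row=c.row, score=c.score,
                 provenance=c.provenance, box_id=c.box_id)
            for c in kept
        ]
    )
    centers.to_csv(out / "plant_centers.csv", index=False)
    return dict(
        template_correlation=model.sample_correlation,
        n_candidates=len(candidates), n_outside=n_outside,
        n_centers=len(kept), n_polygons=len(polys),
        n_empty_boxes=len(empty_boxes),
    )


def _load_polygons(out: Path):
    gj = json.loads((out / "plant_polygons.geojson").read_text())
    polys = []
    for f in gj["features"]:
        p = f["properties"]
        polys.append(
            detection.PlantPolygon(
                plant_id=p["plant_id"], box_id=p["box_id"],
                position=p["position"],
                x0=p["x0"], y0=p["y0"], x1=p["x1"], y1=p["y1"],
                center_col=p["center_col"], center_row=p["center_row"],
            )
        )
    return polys


def stage_extract(config: RunConfig, out: Path) -> dict:
    """Zonal NDVI statistics plus ultrasonic heights -> trait table."""
    rect = read_raster(out / "ndvi_rectified.tif")
    polys = _load_polygons(out)
    ndvi_stats = traits.extract_ndvi_stats(
        rect.data[0], polys, nodata=rect.nodata
    )
    heights = None
    info = dict(n_polygons=len(polys), heights=False)
    if config.track:
        track = pd.read_csv(config.track)
        if len(track):
            rig = SensorRig(mount_height=config.mount_height)
            projected = traits.project_track(track, rig.lateral_offsets)
            mapping = PerspectiveMapping(
                homography=np.load(out / "homography.npy"),
                source_transform=read_raster(out / "ndvi.tif").transform,
                crs=rect.crs,
            )

            def world_to_rect(x, y):
                col, row = mapping.source_transform.inverse(x, y)
                pts = mapping.source_to_rectified(
                    np.column_stack([np.atleast_1d(col), np.atleast_1d(row)])
                )
                return pts[:, 0], pts[:, 1]

            heights = traits.match_heights(
                projected,
                detection.RectIndex(polys, rect.shape),
                world_to_rect,
                mount_height=config.mount_height,
            )
            info.update(
                heights=True,
                n_height_samples=int(heights["n_height_samples"].sum()),
                n_unassigned=heights.attrs["n_unassigned"],
                n_floored=heights.attrs["n_floored"],
            )
            if heights.attrs["n_unassigned"]:
                log.warning(
                    "%d height samples outside all plant polygons",
                    heights.attrs["n_unassigned"],
                )
    table = traits.build_trait_table(ndvi_stats, heights)
    table.to_csv(out / "traits.csv", index=False)
    (out / "traits_meta.json").write_text(
        json.dumps(dict(predictor_definition=traits.PREDICTOR_DEFINITION))
    )
    return info


def _plot_id_for_box(box_id: str, rows_per_plot: int) -> str:
    # box ids are B{block}R{row-in-block}; plots group consecutive rows
    block = int(box_id[1:3])
    row = int(box_id.split("R")[1])
    plot = (row - 1) // rows_per_plot + 1
    return f"B{block:02d}-P{plot:02d}"


def stage_predict(config: RunConfig, out: Path) -> dict:
    """Seasonal biomass prediction per plant, summed to plots."""
    table = pd.read_csv(out / "traits.csv")
    model = SeasonModel(mode=config.season_model_mode)
    if table["ndvisq_ph"].notna().sum() == 0:
        log.warning("no predictor values; prediction skipped")
        return dict(predicted=False)
    table["predicted_g"] = np.where(
        table["ndvisq_ph"].notna(),
        predict_dmy(table["ndvisq_ph"].fillna(0.0), config.season, model),
        np.nan,
    )
    table["season"] = config.season
    table["mode"] = model.mode
    table["plot_id"] = [
        _plot_id_for_box(b, config.rows_per_plot)
        for b in table["plant_id"].str.split("P").str[0]
    ]
    table[
        ["plant_id", "plot_id", "season", "ndvisq_ph", "predicted_g", "mode"]
    ].to_csv(out / "predictions_plants.csv", index=False)
    plants = table.rename(columns={"plant_id": "plant_id"})
    plants["entry"] = None
    plot_pred = aggregate_plot(
        plants[["plant_id", "plot_id", "predicted_g", "entry"]]
    )
    plot_pred["season"] = config.season
    plot_pred.to_csv(out / "predictions_plots.csv", index=False)
    return dict(
        predicted=True, n_plants=int(table["predicted_g"].notna().sum()),
        n_plots=len(plot_pred),
        predictions_per_plot=plot_pred["n_plants"].value_counts().to_dict(),
    )


def stage_validate(config: RunConfig, out: Path) -> dict:
    """Measured-vs-predicted regression at plot level."""
    if not config.harvest:
        return dict(validated=False)
    pred = pd.read_csv(out / "predictions_plots.csv")
    meas = pd.read_csv(config.harvest)
    merged = pred.merge(meas[["plot_id", "measured_kg"]], on="plot_id")
    if len(merged) < 3:
        raise StageError("validate", "fewer than 3 plots with measured DMY")
    report = validate(
        merged["predicted_kg"].to_numpy(), merged["measured_kg"].to_numpy()
    )
    merged.to_csv(out / "validation_pairs.csv", index=False)
    (out / "validation.json").write_text(json.dumps(report.to_dict(), indent=2))
    return dict(validated=True, **report.to_dict())


STAGES = (
    ("calibrate", stage_calibrate),
    ("segment", stage_segment),
    ("detect", stage_detect),
    ("extract", stage_extract),
    ("predict", stage_predict),
    ("validate", stage_validate),
)


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the staged workflow and write a manifest; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(
        seed=config.seed,
        season=config.season,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        stages={},
    )
    wanted = set(stages) if stages else {name for name, _ in STAGES}
    for name, fn in STAGES:
        if name not in wanted:
            continue
        t0 = time.perf_counter()
        try:
            info = fn(config, out)
        except StageError:
            raise
        except Exception as exc:  # surface the failing stage
            raise StageError(name, str(exc)) from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info
        log.info("stage %s done in %.1fs: %s", name, info["seconds"], info)
    # hash excludes wall-clock timings so identical reruns hash identically
    hashable = json.loads(json.dumps(manifest, default=str))
    for info in hashable["stages"].values():
        info.pop("seconds", None)
    blob = json.dumps(hashable, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return manifest
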