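"""Plant-block and plant-row segmentation from projection profiles.

The rectified vegetation-index image of a spaced-plant trial has a strongly
banded structure: blocks are horizontal bands separated by bare-soil
alleys, and within a block each plant row is a vertical strip separated by
bare inter-row soil.  Both are found the same way:

1. project the image onto one axis (sum of pixel values),
2. smooth the profile with a 1-D grayscale opening (line structuring
   element of length ``feature/2``), then erode with a line of length
   ``feature/3`` — the erosion deliberately widens the troughs so the
   initial boxes *under*-estimate each row,
3. take the regional minima of the processed profile; trough centres
   become dividing lines, trough edges bound the initial boxes.

The under-estimated boxes are then extended toward each other by the
box-growing procedure (:func:`grow_boxes`): the gap between two vertically
adjacent boxes is scanned from both ends, repeatedly assigning the
brighter end row to its box until the pixel mass remaining in the gap
falls below a threshold scaled from the mean background intensity.

All pixel rectangles are half-open ``[x0, x1) x [y0, y1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ProjectionProfile",
    "Trough",
    "RowBox",
    "SegmentationParams",
    "project",
    "opening_1d",
    "erosion_1d",
    "regional_minima",
    "process_profile",
    "detect_blocks",
    "detect_rows",
    "initial_row_boxes",
    "grow_boxes",
    "link_and_grow",
    "select_consensus",
    "shifted_ndvi",
]


@dataclass(frozen=True)
class ProjectionProfile:
    """1-D projection of an image region.

    ``axis="y"``: values[i] is the sum of pixel row i (profile runs down
    the image); ``axis="x"``: values[j] is the sum of pixel column j.
    """

    axis: str
    values: np.ndarray
    offset: int = 0  # index of values[0] in full-image coordinates


@dataclass(frozen=True)
class Trough:
    """A regional minimum run: centre index and inclusive edge indices."""

    center: int
    left_edge: int
    right_edge: int


@dataclass(frozen=True)
class SegmentationParams:
    """External parameters of the profile segmentation.

    ``row_length_px`` — expected plant-row length (the only parameter the
    block stage needs); ``plant_width_px`` — expected plant diameter, used
    in place of the row length when splitting a block into rows;
    ``background_t`` — mean background (non-plant) intensity for box
    growing, or None to estimate it from the image.
    """

    row_length_px: int
    plant_width_px: int
    background_t: float | None = None
    grow_variant: str = "prose"

    def __post_init__(self):
        if self.row_length_px <= 0 or self.plant_width_px <= 0:
            raise ValueError("feature lengths must be positive")


@dataclass
class RowBox:
    """Axis-aligned plant-row rectangle in rectified pixel coordinates."""

    block_index: int
    row_index: int
    x0: int
    y0: int
    x1: int
    y1: int
    grown_top: int = 0
    grown_bottom: int = 0

    @property
    def id(self) -> str:
        return f"B{self.block_index + 1:02d}R{self.row_index + 1:03d}"

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def contains(self, col: float, row: float) -> bool:
        return self.x0 <= col < self.x1 and self.y0 <= row < self.y1


@dataclass(frozen=True)
class BlockBand:
    """Horizontal block band: full extent plus trough-edge core extent."""

    index: int
    y0: int
    y1: int        # band between trough centres / image borders
    core_y0: int
    core_y1: int   # trough-edge-to-trough-edge (initial-box extent)


def shifted_ndvi(grid, nodata=-9999.0):
    """NDVI + 1 with nodata mapped to 0, so projections sum non-negative mass."""
    g = np.asarray(grid, dtype=np.float64)
    out = g + 1.0
    out[g == nodata] = 0.0
    return out


def project(region, axis: str) -> ProjectionProfile:
    """Exact projection sums of a 2-D region along one axis."""
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("cannot project an empty region")
    if axis == "y":
        values = region.sum(axis=1, dtype=np.float64)
    elif axis == "x":
        values = region.sum(axis=0, dtype=np.float64)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return ProjectionProfile(axis=axis, values=values)


def _odd_se(length: int) -> int:
    """Force a structuring-element length odd (L -> L-1 if even), min 1."""
    length = int(length)
    if length < 1:
        return 1
    return length if length % 2 == 1 else length - 1


def erosion_1d(values, se_length: int) -> np.ndarray:
    """Flat 1-D grayscale erosion with a centred line SE, clipped at borders."""
    se_length = _odd_se(se_length)
    if se_length <= 1:
        return np.asarray(values, dtype=np.float64).copy()
    return ndimage.grey_erosion(
        np.asarray(values, dtype=np.float64), size=se_length, mode="nearest"
    )


def opening_1d(values, se_length: int) -> np.ndarray:
    """Flat 1-D grayscale opening (erosion then dilation), clipped at borders."""
    se_length = _odd_se(se_length)
    if se_length <= 1:
        return np.asarray(values, dtype=np.float64).copy()
    return ndimage.grey_opening(
        np.asarray(values, dtype=np.float64), size=se_length, mode="nearest"
    )


def regional_minima(values) -> list[Trough]:
    """Maximal constant runs strictly lower than both neighbouring values.

    Image borders count as +inf neighbours, so a low run touching the
    border is a minimum.  The centre is the lower-median index of the run.
    """
    v = np.asarray(values, dtype=np.float64)
    n = len(v)
    if n == 0:
        return []
    troughs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] > v[i]
        right_ok = j == n - 1 or v[j + 1] > v[i]
        # a run spanning the whole profile has no interior structure
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            troughs.append(Trough(center=(i + j) // 2, left_edge=i, right_edge=j))
        i = j + 1
    return troughs


def processed_profile(values, feature_length: int) -> np.ndarray:
    """Opening then erosion of a profile, SE lengths tied to feature size."""
    values = np.asarray(values, dtype=np.float64)
    if feature_length < 2:
        raise ValueError("feature_length must be >= 2")
    se_open = _odd_se(feature_length // 2)
    se_erode = _odd_se(feature_length // 3)
    if len(values) < max(se_open, se_erode):
        raise ValueError(
            f"profile of length {len(values)} shorter than structuring "
            f"element ({max(se_open, se_erode)})"
        )
    return erosion_1d(opening_1d(values, se_open), se_erode)


def process_profile(profile, feature_length: int) -> list[Trough]:
    """Open, erode and locate the regional minima of a projection profile.

    ``feature_length`` is the expected extent of the bright features
    (plant-row length for block finding, plant width for row finding); the
    opening uses a line SE of length ``feature_length // 2`` and the
    erosion ``feature_length // 3``, each forced odd.
    """
    values = profile.values if isinstance(profile, ProjectionProfile) else profile
    return regional_minima(processed_profile(values, feature_length))


def trough_prominence(processed, trough: Trough) -> float:
    """Topographic prominence of one minimum run.

    Walk outward from the run until terrain drops below the trough value
    (or the border); the prominence is the lower of the two highest ridges
    reached.  Shallow noise minima sitting next to a deeper trough in the
    same gap get small prominence and can be discarded.
    """
    v = np.asarray(processed, dtype=np.float64)
    depth = v[trough.center]
    left_max = depth
    for i in range(trough.left_edge - 1, -1, -1):
        if v[i] < depth:
            break
        left_max = max(left_max, v[i])
    right_max = depth
    for i in range(trough.right_edge + 1, len(v)):
        if v[i] < depth:
            break
        right_max = max(right_max, v[i])
    return float(min(left_max, right_max) - depth)


def significant_troughs(
    processed, troughs, rel_prominence: float = 0.1
) -> list[Trough]:
    """Keep troughs whose prominence exceeds a fraction of the profile range."""
    v = np.asarray(processed, dtype=np.float64)
    span = float(np.ptp(v))
    if span == 0:
        return list(troughs)
    cut = rel_prominence * span
    return [t for t in troughs if trough_prominence(v, t) >= cut]


def _intervals_from_troughs(troughs, length: int):
    """Half-open intervals between consecutive trough centres and borders."""
    cuts = [0] + [t.center for t in troughs] + [length]
    # trough centres at the very border do not create empty intervals
    cuts = sorted(set(min(max(c, 0), length) for c in cuts))
    return [(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


def _drop_border_troughs(troughs, length: int):
    """Discard minimum runs touching the profile border.

    A run at the border reflects the crop boundary, not a gap between two
    features, so it must not become a dividing line.
    """
    return [
        t for t in troughs if t.left_edge > 0 and t.right_edge < length - 1
    ]


def detect_blocks(
    image, params: SegmentationParams, n_expected: int | None = None
) -> list[BlockBand]:
    """Find horizontal block bands of a rectified vegetation-index image.

    The y-projection profile is processed with the expected plant-row
    length; trough centres become the dividing lines and trough edges the
    core (initial-box) extents.
    """
    img = np.asarray(image, dtype=np.float64)
    prof = project(img, axis="y")
    proc = processed_profile(prof.values, params.row_length_px)
    troughs = _drop_border_troughs(regional_minima(proc), len(proc))
    troughs = significant_troughs(proc, troughs)
    if not troughs and n_expected is not None and n_expected > 1:
        warnings.warn(
            f"no block dividers found where {n_expected} blocks expected; "
            "returning a single block"
        )
    height = img.shape[0]
    intervals = _intervals_from_troughs(troughs, height)
    # core extents: from the inner edge of the trough above to the inner
    # edge of the trough below (image borders where there is no trough)
    edges_above = [0] + [t.right_edge + 1 for t in troughs]
    edges_below = [t.left_edge for t in troughs] + [height]
    bands = []
    for idx, (y0, y1) in enumerate(intervals):
        core_y0 = max(y0, edges_above[min(idx, len(edges_above) - 1)])
        core_y1 = min(y1, edges_below[min(idx, len(edges_below) - 1)])
        if core_y1 <= core_y0:  # fully eroded band; fall back to the band
            core_y0, core_y1 = y0, y1
        bands.append(
            BlockBand(index=idx, y0=y0, y1=y1, core_y0=core_y0, core_y1=core_y1)
        )
    return bands


def detect_rows(
    image, band: BlockBand, params: SegmentationParams,
    empty_rel_ptp: float = 0.05,
) -> list[tuple[int, int]]:
    """Split one block band into plant-row x-intervals.

    Same profile processing as block finding, with the plant width as the
    feature length and the projection taken along x.  A band whose profile
    is essentially flat (no vegetation contrast) yields no rows.
    """
    img = np.asarray(image, dtype=np.float64)
    sub = img[band.y0:band.y1]
    prof = project(sub, axis="x")
    v = prof.values
    mean = float(np.mean(v))
    if mean <= 0 or float(np.ptp(v)) / max(mean, 1e-12) < empty_rel_ptp:
        warnings.warn(f"block {band.index}: no vegetation contrast, 0 rows")
        return []
    proc = processed_profile(v, params.plant_width_px)
    troughs = _drop_border_troughs(regional_minima(proc), len(proc))
    troughs = significant_troughs(proc, troughs)
    return _intervals_from_troughs(troughs, img.shape[1])


def initial_row_boxes(bands, rows_per_band) -> list[RowBox]:
    """One under-estimated box per (block, row).

    ``rows_per_band`` maps each band (by list position) to its row
    x-intervals.  Vertical extent is the band's trough-edge core extent.
    """
    boxes = []
    for band, intervals in zip(bands, rows_per_band):
        for r, (x0, x1) in enumerate(intervals):
            boxes.append(
                RowBox(
                    block_index=band.index, row_index=r,
                    x0=int(x0), y0=int(band.core_y0),
                    x1=int(x1), y1=int(band.core_y1),
                )
            )
    return boxes


def grow_boxes(f, t: float, width: int, variant: str = "printed"):
    """Split the gap profile between two linked boxes.

    ``f`` is the row-wise pixel-sum profile of the linking region (f[0] on
    the bottom edge of the top box, f[-1] on the top edge of the bottom
    box), ``t`` the mean background per-pixel intensity and ``width`` the
    link width in pixels.  Rows are consumed from whichever end is
    currently brighter until the mass remaining in the gap drops below
    ``t * width * n_remaining``; ties consume both ends.

    ``variant="printed"`` counts the remaining rows as ``n - j + 1``
    (which includes rows already granted to the bottom box);
    ``variant="prose"`` counts only the rows still between the two growing
    edges, ``k - j + 1``.

    Returns ``(rows added to the bottom edge of the top box,
    rows added to the top edge of the bottom box)``.
    """
    f = np.asarray(f, dtype=np.float64)
    n = len(f)
    if t <= 0:
        raise ValueError("background threshold t must be positive")
    if width < 1:
        raise ValueError("link width must be >= 1")
    if variant not in ("printed", "prose"):
        raise ValueError("variant must be 'printed' or 'prose'")
    if n == 0:
        return 0, 0
    j, k = 1, n       # 1-based indices as in the procedure
    a = 0.0
    s = float(f.sum())
    while j < k:
        fj, fk = f[j - 1], f[k - 1]
        if fj > fk:
            a += fj
            j += 1
        elif fj == fk:
            a += fj + fk
            j += 1
            k -= 1
        else:
            a += fk
            k -= 1
        remaining = (n - j + 1) if variant == "printed" else (k - j + 1)
        t1 = t * width * remaining
        if s - a <= t1:
            break
    return j - 1, n - k


@dataclass
class LinkRecord:
    """One link between vertically adjacent boxes, for reporting."""

    top_id: str
    bottom_id: str
    n_rows: int
    width: int
    grown_top: int
    grown_bottom: int


def estimate_background(image, boxes, quantile: float = 0.25) -> float:
    """Background (non-plant) intensity from pixels outside every box.

    The region outside the initial boxes is exactly where not-yet-assigned
    plants sit, so a plain mean over it is biased upward by plant pixels.
    A low quantile of the outside pixels lands inside the soil population
    and estimates the mean background robustly; a slight low bias is safe
    (growth stops at soil level regardless) whereas a high bias strands
    plants outside the grown boxes.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.ones(img.shape, dtype=bool)
    for b in boxes:
        mask[b.y0:b.y1, b.x0:b.x1] = False
    if not mask.any():
        raise ValueError("no background pixels outside the initial boxes")
    return float(np.percentile(img[mask], 100 * quantile))


def link_and_grow(
    boxes, image, t: float | None = None, variant: str = "prose"
):
    """Grow every box into the gaps above/below it.

    Links join each box with the box of maximal x-overlap in the adjacent
    block above and below (at most two links per box).  Boxes on the field
    boundary grow only through their single link.  Returns
    ``(grown boxes, link records, t used)``.
    """
    img = np.asarray(image, dtype=np.float64)
    if t is None:
        t = estimate_background(img, boxes)
    by_block: dict[int, list[RowBox]] = {}
    for b in boxes:
        by_block.setdefault(b.block_index, []).append(b)
    grown = {id(b): [b.y0, b.y1] for b in boxes}
    records = []
    block_ids = sorted(by_block)
    for bi in block_ids:
        if bi + 1 not in by_block:
            continue
        uppers = by_block[bi]
        lowers = by_block[bi + 1]
        for top in uppers:
            # best x-overlap partner in the block below
            best, best_ov = None, 0
            for bot in lowers:
                ov = min(top.x1, bot.x1) - max(top.x0, bot.x0)
                if ov > best_ov:
                    best, best_ov = bot, ov
            if best is None:
                continue
            bot = best
            lx0, lx1 = max(top.x0, bot.x0), min(top.x1, bot.x1)
            width = lx1 - lx0
            n = bot.y0 - top.y1
            if n <= 0 or width <= 0:
                continue
            f = img[top.y1:bot.y0, lx0:lx1].sum(axis=1)
            add_top, add_bottom = grow_boxes(f, t=t, width=width, variant=variant)
            grown[id(top)][1] += add_top
            grown[id(bot)][0] -= add_bottom
            records.append(
                LinkRecord(
                    top_id=top.id, bottom_id=bot.id, n_rows=n, width=width,
                    grown_top=add_top, grown_bottom=add_bottom,
                )
            )
    out = []
    for b in boxes:
        y0, y1 = grown[id(b)]
        out.append(
            replace(
                b, y0=int(y0), y1=int(y1),
                grown_top=b.y0 - int(y0), grown_bottom=int(y1) - b.y1,
            )
        )
    return out, records, t


def select_consensus(candidate_sets):
    """Pick the polygon set whose areas have the least sample variance.

    ``candidate_sets`` is a sequence of ``(label, boxes)``; ties go to the
    earliest set.  Returns ``(label, boxes, report)`` where the report is a
    list of ``(label, n_polygons, area_variance)``.
    """
    candidate_sets = list(candidate_sets)
    if not candidate_sets:
        raise ValueError("no candidate polygon sets")
    counts = {len(boxes) for _, boxes in candidate_sets}
    if len(counts) > 1:
        warnings.warn(f"candidate sets differ in polygon count: {sorted(counts)}")
    report = []
    for label, boxes in candidate_sets:
        areas = np.asarray([b.area for b in boxes], dtype=np.float64)
        var = float(np.var(areas, ddof=1)) if len(areas) > 1 else 0.0
        report.append((label, len(boxes), var))
    best = min(range(len(report)), key=lambda i: report[i][2])
    label, boxes = candidate_sets[best]
    return label, boxes, report
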