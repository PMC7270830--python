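"""Individual plant detection and per-plant polygon construction.

Plant centres are found by matching a mean-of-samples template against the
vegetation-index image with zero-normalised cross-correlation; local
maxima above a score threshold survive a non-maximum suppression at the
ground-truth tolerance.  Centres outside every plant-row box are
discarded, file-driven manual edits are applied, and each row box is then
split into per-plant rectangles at the midpoints between adjacent centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template as _skimage_match_template

__all__ = [
    "TemplateModel",
    "PlantCenter",
    "PlantPolygon",
    "build_template",
    "match_template",
    "filter_and_qc",
    "split_row_polygon",
    "split_all",
]


@dataclass
class TemplateModel:
    """Mean-of-samples matching template.

    ``context`` extra pixels are appended around the nominal sample window
    when sampling and matching (a 20x20 window with context 4 matches as
    28x28), giving the correlator a ring of background to lock onto.
    """

    template: np.ndarray
    width: int = 20
    height: int = 20
    context: int = 4
    threshold: float = 0.6
    tolerance_px: int = 3
    sample_correlation: float = float("nan")

    def __post_init__(self):
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class PlantCenter:
    col: float
    row: float
    score: float
    provenance: str = "matched"   # matched | manual-add
    status: str = "kept"          # kept | removed
    box_id: str | None = None


@dataclass(frozen=True)
class PlantPolygon:
    """Per-plant half-open rectangle, a slice of its row box."""

    plant_id: str
    box_id: str
    position: int       # 1-based index along the row
    x0: int
    y0: int
    x1: int
    y1: int
    center_col: float = float("nan")
    center_row: float = float("nan")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


def _extract_window(image, col, row, half_w, half_h):
    c, r = int(round(col)), int(round(row))
    win = image[r - half_h: r + half_h + 1, c - half_w: c + half_w + 1]
    return win


def build_template(
    image, sample_centers, width=20, height=20, context=4,
    threshold=0.6, tolerance_px=3,
) -> TemplateModel:
    """Average sample windows centred on hand-picked plants into a template.

    All samples must fit inside the image with their context margin; the
    reported sample correlation is the mean Pearson correlation between
    the finished template and each contributing sample.
    """
    image = np.asarray(image, dtype=np.float64)
    half_w = (width + 2 * context) // 2
    half_h = (height + 2 * context) // 2
    wins = []
    for col, row in sample_centers:
        win = _extract_window(image, col, row, half_w, half_h)
        if win.shape != (2 * half_h + 1, 2 * half_w + 1):
            raise ValueError(
                f"sample at ({col}, {row}) does not fit in the image with "
                f"its context margin"
            )
        wins.append(win)
    if len(wins) < 2:
        raise ValueError("need at least 2 samples to build a template")
    stack = np.stack(wins)
    template = stack.mean(axis=0)
    t = template.ravel() - template.mean()
    corrs = []
    for win in wins:
        w = win.ravel() - win.mean()
        denom = np.linalg.norm(t) * np.linalg.norm(w)
        corrs.append(float(t @ w / denom) if denom > 0 else 0.0)
    return TemplateModel(
        template=template, width=width, height=height, context=context,
        threshold=threshold, tolerance_px=tolerance_px,
        sample_correlation=float(np.mean(corrs)),
    )


def match_template(image, model: TemplateModel, region=None) -> list[PlantCenter]:
    """Scan the image with the template and return candidate plant centres.

    Zero-normalised cross-correlation is evaluated at every valid window
    position; strict local maxima with score >= threshold are kept, then
    detections closer than the tolerance are merged keeping the higher
    score (ties keep the smaller (row, col)).
    """
    image = np.asarray(image, dtype=np.float64)
    x0 = y0 = 0
    if region is not None:
        x0, y0, x1, y1 = region
        image = image[y0:y1, x0:x1]
    th, tw = model.template.shape
    if image.shape[0] < th or image.shape[1] < tw:
        raise ValueError(
            f"search region {image.shape} smaller than template ({th}, {tw})"
        )
    # reflective padding keeps border plants matchable: the score grid then
    # aligns with window centres (score[r, c] scores a window centred there)
    score = _skimage_match_template(
        image, model.template, pad_input=True, mode="reflect"
    )
    # local maxima (plateau-tolerant) above threshold
    maxf = ndimage.maximum_filter(score, size=2 * model.tolerance_px + 1)
    cand = np.argwhere((score >= model.threshold) & (score >= maxf))
    # strongest first; score ties resolved toward smaller (row, col)
    order = np.lexsort(
        (cand[:, 1], cand[:, 0], -score[cand[:, 0], cand[:, 1]])
    )
    cand = cand[order]
    # greedy non-maximum suppression on a hash grid (cell = tolerance) so
    # the scan stays linear in the number of candidates
    kept: list[tuple[int, int, float]] = []
    tol = float(model.tolerance_px)
    tol2 = tol * tol
    cell = max(1, model.tolerance_px)
    occupied: dict[tuple[int, int], list[int]] = {}
    for r, c in cand:
        gr, gc = int(r // cell), int(c // cell)
        ok = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for idx in occupied.get((gr + dr, gc + dc), ()):
                    kr, kc, _ = kept[idx]
                    if (kr - r) ** 2 + (kc - c) ** 2 <= tol2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            occupied.setdefault((gr, gc), []).append(len(kept))
            kept.append((int(r), int(c), float(score[r, c])))
    kept.sort(key=lambda t: (t[0], t[1]))
    return [
        PlantCenter(col=c + x0, row=r + y0, score=s) for r, c, s in kept
    ]


class RectIndex:
    """O(1) point-in-rectangle lookup via a rasterised label grid.

    Rectangles must be pairwise disjoint (they are: row boxes in one block
    are disjoint and blocks do not overlap after growing; plant polygons
    partition their boxes).
    """

    def __init__(self, rects, shape):
        self.rects = list(rects)
        self.label = np.full(shape, -1, dtype=np.int32)
        for i, b in enumerate(self.rects):
            y0, y1 = max(0, b.y0), min(shape[0], b.y1)
            x0, x1 = max(0, b.x0), min(shape[1], b.x1)
            self.label[y0:y1, x0:x1] = i

    def find(self, col, row):
        r, c = int(row), int(col)
        if 0 <= r < self.label.shape[0] and 0 <= c < self.label.shape[1]:
            i = self.label[r, c]
            if i >= 0:
                return self.rects[i]
        return None


def _find_box(boxes, col, row):
    if isinstance(boxes, RectIndex):
        return boxes.find(col, row)
    for b in boxes:
        if b.contains(col, row):
            return b
    return None


def filter_and_qc(candidates, boxes, edits=None, image_shape=None):
    """Keep centres inside row boxes and apply manual add/remove edits.

    ``edits`` is a sequence of ``(action, col, row)`` with action ``add``
    or ``remove``; a remove matches the nearest kept detection within 3 px.
    Returns ``(kept centres with box assignment, n_discarded_outside)``.
    """
    kept = []
    n_outside = 0
    for c in candidates:
        box = _find_box(boxes, c.col, c.row)
        if box is None:
            n_outside += 1
            continue
        kept.append(
            PlantCenter(
                col=c.col, row=c.row, score=c.score,
                provenance=c.provenance, status="kept", box_id=box.id,
            )
        )
    for i, edit in enumerate(edits or []):
        action, col, row = edit[0], float(edit[1]), float(edit[2])
        if image_shape is not None and not (
            0 <= col < image_shape[1] and 0 <= row < image_shape[0]
        ):
            raise ValueError(
                f"edit {i} ({action} at {col}, {row}) outside the image"
            )
        if action == "add":
            box = _find_box(boxes, col, row)
            if box is None:
                raise ValueError(
                    f"edit {i}: manual add at ({col}, {row}) lies in no row box"
                )
            kept.append(
                PlantCenter(col=col, row=row, score=float("nan"),
                            provenance="manual-add", box_id=box.id)
            )
        elif action == "remove":
            best, best_d = None, 9.0 + 1e-9
            for j, c in enumerate(kept):
                d = (c.col - col) ** 2 + (c.row - row) ** 2
                if d <= 9.0 and d < best_d:
                    best, best_d = j, d
            if best is not None:
                kept.pop(best)
        else:
            raise ValueError(f"edit {i}: unknown action {action!r}")
    return kept, n_outside


def split_row_polygon(box, centers, plant_id_prefix=None) -> list[PlantPolygon]:
    """Split one row box into per-plant rectangles at centre midpoints.

    Cut lines sit at the rounded midpoints between consecutive centres
    (sorted along the row axis, y); the first and last polygons run to the
    box ends.  The polygons partition the box exactly and each contains
    its own centre.  Returns [] for an empty box (flagged upstream).
    """
    if not centers:
        return []
    prefix = plant_id_prefix or box.id
    cs = sorted(centers, key=lambda c: (c.row, c.col))
    ys = [c.row for c in cs]
    cuts = [box.y0]
    for a, b in zip(ys[:-1], ys[1:]):
        cut = int(round((a + b) / 2.0))
        # keep each centre inside its own half-open slice where the pixel
        # grid allows it (centres in the same pixel cannot be separated)
        lo = int(np.floor(a)) + 1
        hi = max(lo, int(np.floor(b)))
        cuts.append(min(max(cut, lo), hi))
    cuts.append(box.y1)
    # guard: monotone cuts inside the box
    for i in range(1, len(cuts)):
        cuts[i] = min(max(cuts[i], cuts[i - 1]), box.y1)
    polys = []
    for i, c in enumerate(cs):
        polys.append(
            PlantPolygon(
                plant_id=f"{prefix}P{i + 1:02d}",
                box_id=box.id, position=i + 1,
                x0=box.x0, y0=cuts[i], x1=box.x1, y1=cuts[i + 1],
                center_col=c.col, center_row=c.row,
            )
        )
    return polys


def split_all(boxes, centers) -> tuple[list[PlantPolygon], list[str]]:
    """Split every row box; returns (polygons, ids of empty boxes)."""
    by_box: dict[str, list[PlantCenter]] = {}
    for c in centers:
        if c.box_id is not None:
            by_box.setdefault(c.box_id, []).append(c)
    polys = []
    empty = []
    for box in boxes:
        cs = by_box.get(box.id, [])
        if not cs:
            empty.append(box.id)
            continue
        polys.extend(split_row_polygon(box, cs))
    return polys, empty
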