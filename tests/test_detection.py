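import numpy as np
import pytest

from phenorow import detection
from phenorow.segmentation import RowBox


def gaussian_blob(shape, center, sigma=2.5, peak=1.0):
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return peak * np.exp(
        -((xx - center[0]) ** 2 + (yy - center[1]) ** 2) / (2 * sigma**2)
    )


class TestBuildTemplate:
    def test_identical_samples_give_perfect_correlation(self):
        img = np.zeros((60, 60))
        img += gaussian_blob(img.shape, (20, 20))
        img += gaussian_blob(img.shape, (40, 40))
        model = detection.build_template(
            img, [(20, 20), (40, 40)], width=10, height=10, context=2
        )
        assert model.sample_correlation == pytest.approx(1.0, abs=1e-9)
        assert model.template.shape == (15, 15)

    def test_template_is_pixelwise_mean(self):
        rng = np.random.default_rng(0)
        img = np.zeros((80, 40))
        img += gaussian_blob(img.shape, (20, 20))
        img += gaussian_blob(img.shape, (20, 60))
        noise = rng.normal(0, 0.05, img.shape)
        img = img + noise
        model = detection.build_template(
            img, [(20, 20), (20, 60)], width=10, height=10, context=2
        )
        w1 = img[13:28, 13:28]
        w2 = img[53:68, 13:28]
        np.testing.assert_allclose(model.template, (w1 + w2) / 2, atol=1e-12)

    def test_sample_not_fitting_rejected(self):
        img = np.zeros((30, 30))
        with pytest.raises(ValueError, match="fit"):
            detection.build_template(img, [(2, 2), (15, 15)])

    def test_single_sample_rejected(self):
        img = np.zeros((60, 60))
        with pytest.raises(ValueError, match="2 samples"):
            detection.build_template(img, [(30, 30)])


class TestMatchTemplate:
    def make_model(self, sigma=2.5):
        canvas = np.zeros((41, 41))
        canvas += gaussian_blob(canvas.shape, (20, 20), sigma=sigma)
        canvas2 = canvas * 0.7
        return detection.build_template(
            canvas + 0.0, [(20, 20)] * 0 + [(20, 20), (20, 20)],
            width=10, height=10, context=2,
        )

    def test_blank_image_yields_nothing(self):
        model = self.make_model()
        img = np.full((50, 50), 0.3)
        assert detection.match_template(img, model) == []

    def test_single_paste_detected_at_location(self):
        model = self.make_model()
        img = np.zeros((60, 60))
        img += gaussian_blob(img.shape, (33, 24), sigma=2.5)
        found = detection.match_template(img, model)
        assert len(found) == 1
        c = found[0]
        assert (c.col, c.row) == (33, 24)
        assert c.score == pytest.approx(1.0, abs=1e-6)

    def test_region_smaller_than_template_rejected(self):
        model = self.make_model()
        with pytest.raises(ValueError, match="smaller"):
            detection.match_template(np.zeros((5, 5)), model)

    def test_row_of_plants_fully_recovered(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.05, 0.15, (420, 40))
        truth = [(20, 6 + int(round(12.5 * i))) for i in range(32)]
        for cx, cy in truth:
            img = np.maximum(img, gaussian_blob(img.shape, (cx, cy), sigma=3, peak=0.7))
        model = detection.build_template(img, truth[5:10], width=20, height=20, context=4)
        found = detection.match_template(img, model)
        assert len(found) == 32
        for (cx, cy), c in zip(truth, sorted(found, key=lambda c: c.row)):
            assert abs(c.col - cx) <= 3 and abs(c.row - cy) <= 3


class TestFilterAndQc:
    def boxes(self):
        return [
            RowBox(block_index=0, row_index=0, x0=0, y0=0, x1=20, y1=100),
            RowBox(block_index=0, row_index=1, x0=30, y0=0, x1=50, y1=100),
        ]

    def center(self, col, row):
        return detection.PlantCenter(col=col, row=row, score=0.9)

    def test_outside_candidates_discarded(self):
        kept, n_out = detection.filter_and_qc(
            [self.center(10, 10), self.center(25, 10)], self.boxes()
        )
        assert len(kept) == 1 and n_out == 1
        assert kept[0].box_id == "B01R001"

    def test_manual_add_and_remove(self):
        kept, _ = detection.filter_and_qc(
            [self.center(10, 10), self.center(40, 50)],
            self.boxes(),
            edits=[("add", 35, 20), ("remove", 11, 11)],
            image_shape=(100, 60),
        )
        assert {(c.col, c.row) for c in kept} == {(40, 50), (35, 20)}
        added = [c for c in kept if c.provenance == "manual-add"]
        assert len(added) == 1 and added[0].box_id == "B01R002"

    def test_edit_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            detection.filter_and_qc(
                [], self.boxes(), edits=[("add", 500, 5)], image_shape=(100, 60)
            )

    def test_rect_index_equivalent_to_linear_scan(self):
        boxes = self.boxes()
        cands = [self.center(c, r) for c in (5, 25, 45) for r in (0, 50, 99)]
        linear, n1 = detection.filter_and_qc(cands, boxes)
        indexed, n2 = detection.filter_and_qc(
            cands, detection.RectIndex(boxes, (100, 60))
        )
        assert n1 == n2
        assert [(c.col, c.row, c.box_id) for c in linear] == [
            (c.col, c.row, c.box_id) for c in indexed
        ]


class TestSplitRowPolygon:
    def box(self, y1=30):
        return RowBox(block_index=0, row_index=0, x0=0, y0=0, x1=10, y1=y1)

    def centers(self, ys):
        return [detection.PlantCenter(col=5, row=y, score=1.0) for y in ys]

    def test_midpoint_cuts(self):
        polys = detection.split_row_polygon(self.box(), self.centers([5, 15, 25]))
        assert [(p.y0, p.y1) for p in polys] == [(0, 10), (10, 20), (20, 30)]
        assert [p.position for p in polys] == [1, 2, 3]
        assert polys[0].plant_id == "B01R001P01"

    def test_single_centre_takes_whole_box(self):
        polys = detection.split_row_polygon(self.box(), self.centers([12]))
        assert len(polys) == 1
        assert (polys[0].y0, polys[0].y1) == (0, 30)

    def test_32_equal_polygons(self):
        box = RowBox(0, 0, x0=0, y0=0, x1=10, y1=400)
        ys = [6.25 + 12.5 * i for i in range(32)]
        polys = detection.split_row_polygon(box, self.centers(ys))
        assert len(polys) == 32
        widths = {p.y1 - p.y0 for p in polys}
        assert widths == {12, 13}  # 12.5 px pitch on an integer grid
        assert sum(p.area for p in polys) == box.area

    def test_zero_centres_flagged_not_split(self):
        assert detection.split_row_polygon(self.box(), []) == []

    def test_partition_property_random_centres(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y1 = int(rng.integers(10, 200))
            box = RowBox(0, 0, x0=0, y0=0, x1=7, y1=y1)
            # detected centres are never closer than the NMS tolerance
            n = int(rng.integers(1, max(2, min(12, y1 // 8))))
            while True:
                ys = np.sort(rng.uniform(0, y1, size=n))
                if n == 1 or np.min(np.diff(ys)) >= 3.0:
                    break
            polys = detection.split_row_polygon(box, self.centers(ys))
            assert sum(p.area for p in polys) == box.area
            for p, y in zip(polys, ys):
                assert p.y0 <= y < p.y1 or (y >= p.y1 == box.y1)

    def test_determinism(self):
        polys1 = detection.split_row_polygon(self.box(), self.centers([5, 25]))
        polys2 = detection.split_row_polygon(self.box(), self.centers([25, 5]))
        assert [(p.plant_id, p.y0, p.y1) for p in polys1] == [
            (p.plant_id, p.y0, p.y1) for p in polys2
        ]
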