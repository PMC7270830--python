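import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenorow import segmentation as seg


# --- independent brute-force oracle ---------------------------------------


def sliding_erosion(values, length):
    """Min over a centred window of odd `length`, clipped at the borders."""
    n = len(values)
    half = length // 2
    return np.array(
        [min(values[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )


def sliding_dilation(values, length):
    n = len(values)
    half = length // 2
    return np.array(
        [max(values[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
    )


def brute_minima(values):
    """Runs of equal values strictly below both neighbours (borders +inf)."""
    v = list(values)
    out = []
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[j + 1] == v[i]:
            j += 1
        whole = i == 0 and j == len(v) - 1
        if (
            not whole
            and (i == 0 or v[i - 1] > v[i])
            and (j == len(v) - 1 or v[j + 1] > v[i])
        ):
            out.append(((i + j) // 2, i, j))
        i = j + 1
    return out


def odd(length):
    length = int(length)
    return max(1, length if length % 2 else length - 1)


def brute_process(values, feature_length):
    opened = sliding_dilation(
        sliding_erosion(values, odd(feature_length // 2)),
        odd(feature_length // 2),
    )
    eroded = sliding_erosion(opened, odd(feature_length // 3))
    return brute_minima(eroded)


# --- projection -----------------------------------------------------------


class TestProject:
    def test_row_sums(self):
        prof = seg.project(np.ones((2, 3)), axis="y")
        np.testing.assert_array_equal(prof.values, [3.0, 3.0])

    def test_column_sums(self):
        prof = seg.project(np.ones((2, 3)), axis="x")
        np.testing.assert_array_equal(prof.values, [2.0, 2.0, 2.0])

    def test_zero_image(self):
        prof = seg.project(np.zeros((4, 4)), axis="y")
        assert np.all(prof.values == 0)

    def test_single_column_identity(self):
        col = np.array([[1.0], [5.0], [2.0]])
        prof = seg.project(col, axis="y")
        np.testing.assert_array_equal(prof.values, [1.0, 5.0, 2.0])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            seg.project(np.empty((0, 3)), axis="y")


# --- profile processing ---------------------------------------------------


class TestProcessProfile:
    def test_constant_profile_has_no_troughs(self):
        assert seg.process_profile(np.full(30, 7.0), 6) == []

    def test_single_flat_trough(self):
        # hand-traced: opening (SE 3) is the identity here, erosion SE is
        # forced down to 1, so the minima of the raw profile remain:
        # run indices 3..5, centre 4 (0-based)
        profile = np.array([9, 9, 9, 0, 0, 0, 9, 9, 9], dtype=float)
        troughs = seg.process_profile(profile, 6)
        assert len(troughs) == 1
        t = troughs[0]
        assert (t.center, t.left_edge, t.right_edge) == (4, 3, 5)

    def test_two_separated_troughs_match_oracle(self):
        profile = np.array(
            [9, 9, 9, 0, 0, 9, 9, 9, 9, 9, 1, 1, 1, 9, 9, 9], dtype=float
        )
        got = [
            (t.center, t.left_edge, t.right_edge)
            for t in seg.process_profile(profile, 6)
        ]
        assert got == brute_process(profile, 6)
        assert len(got) == 2

    def test_too_short_profile_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            seg.process_profile(np.array([1.0, 2.0]), 20)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=3), min_size=7, max_size=50),
        feature_length=st.integers(min_value=6, max_value=18),
    )
    def test_matches_bruteforce_oracle(self, values, feature_length):
        values = np.asarray(values, dtype=float)
        if len(values) < max(odd(feature_length // 2), odd(feature_length // 3)):
            return
        got = [
            (t.center, t.left_edge, t.right_edge)
            for t in seg.process_profile(values, feature_length)
        ]
        assert got == brute_process(values, feature_length)


# --- box growing ----------------------------------------------------------


class TestGrowBoxes:
    @pytest.mark.parametrize(
        "f, t, expect",
        [
            ((0, 0, 0, 0, 0), 0.5, (1, 1)),     # equality branch then stop
            ((10, 10, 0, 0, 0), 0.001, (2, 0)),  # two top-heavy steps
            ((8, 0, 0, 0, 8), 0.001, (1, 1)),    # symmetric ends
        ],
    )
    def test_hand_traced_cases(self, f, t, expect):
        assert seg.grow_boxes(np.array(f, float), t=t, width=1) == expect

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            seg.grow_boxes(np.array([1.0]), t=0.0, width=1)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        f=st.lists(st.floats(0, 100), min_size=1, max_size=40),
        t=st.floats(0.01, 10),
        width=st.integers(1, 50),
        variant=st.sampled_from(["printed", "prose"]),
    )
    def test_never_overlaps_and_terminates(self, f, t, width, variant):
        top, bottom = seg.grow_boxes(
            np.array(f), t=t, width=width, variant=variant
        )
        assert top >= 0 and bottom >= 0
        assert top + bottom <= len(f)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        f=st.lists(st.floats(0, 100), min_size=1, max_size=30),
        t=st.floats(0.01, 5),
        factor=st.floats(1.0, 4.0),
        variant=st.sampled_from(["printed", "prose"]),
    )
    def test_growth_monotone_in_threshold(self, f, t, factor, variant):
        """A higher background threshold never grows more rows."""
        lo = seg.grow_boxes(np.array(f), t=t, width=1, variant=variant)
        hi = seg.grow_boxes(np.array(f), t=t * factor, width=1, variant=variant)
        assert sum(hi) <= sum(lo)


# --- consensus ------------------------------------------------------------


def boxes_with_areas(areas):
    return [
        seg.RowBox(block_index=0, row_index=i, x0=0, y0=0, x1=a, y1=1)
        for i, a in enumerate(areas)
    ]


class TestConsensus:
    def test_argmin_variance(self):
        sets = [
            ("d1", boxes_with_areas([1, 5])),    # var 8
            ("d2", boxes_with_areas([3, 4])),    # var 0.5
            ("d3", boxes_with_areas([1, 4])),    # var 4.5
        ]
        label, chosen, report = seg.select_consensus(sets)
        assert label == "d2"
        assert [r[0] for r in report] == ["d1", "d2", "d3"]

    def test_single_candidate(self):
        sets = [("only", boxes_with_areas([2, 2]))]
        label, chosen, _ = seg.select_consensus(sets)
        assert label == "only"

    def test_tie_goes_to_earliest(self):
        sets = [
            ("first", boxes_with_areas([1, 3])),
            ("second", boxes_with_areas([5, 7])),  # same variance 2
        ]
        label, _, _ = seg.select_consensus(sets)
        assert label == "first"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            seg.select_consensus([])

    def test_count_mismatch_warns(self):
        sets = [
            ("a", boxes_with_areas([1, 2])),
            ("b", boxes_with_areas([1, 2, 3])),
        ]
        with pytest.warns(UserWarning, match="differ"):
            seg.select_consensus(sets)


# --- end-to-end segmentation on the synthetic render ----------------------


@pytest.fixture(scope="module")
def segmented(small_layout, small_render):
    from phenorow.calibration import compute_ndvi

    raster, truth, _, _ = small_render
    ndvi = compute_ndvi(raster.band("red"), raster.band("nir"))
    g = small_layout.gsd
    fx0, fy0, fx1, fy1 = [int(round(v / g)) for v in small_layout.field_bbox()]
    img = seg.shifted_ndvi(ndvi[fy0:fy1, fx0:fx1])
    params = seg.SegmentationParams(
        row_length_px=int(small_layout.plot_length / g),
        plant_width_px=int(2 * small_layout.plant_radius / g),
    )
    bands = seg.detect_blocks(img, params, n_expected=small_layout.n_blocks)
    rows = [seg.detect_rows(img, b, params) for b in bands]
    boxes = seg.initial_row_boxes(bands, rows)
    grown, links, t = seg.link_and_grow(boxes, img)
    return img, bands, rows, boxes, grown, (fx0, fy0)



class TestOnSyntheticRender:
    def test_block_and_row_counts_match_layout(
        self, segmented, small_layout
    ):
        _, bands, rows, boxes, _, _ = segmented
        assert len(bands) == small_layout.n_blocks
        assert [len(r) for r in rows] == [small_layout.rows_per_block] * 3
        assert len(boxes) == small_layout.n_rows

    def test_initial_boxes_positive_and_disjoint(self, segmented):
        _, _, _, boxes, _, _ = segmented
        assert all(b.area > 0 for b in boxes)
        by_block = {}
        for b in boxes:
            by_block.setdefault(b.block_index, []).append(b)
        for blist in by_block.values():
            blist.sort(key=lambda b: b.x0)
            for a, b in zip(blist[:-1], blist[1:]):
                assert a.x1 <= b.x0

    def test_every_plant_centre_in_exactly_one_grown_box(
        self, segmented, small_layout, small_truth
    ):
        _, _, _, _, grown, (fx0, fy0) = segmented
        plants, _, _ = small_truth
        cols = plants["x"] / small_layout.gsd - fx0
        rows_ = plants["y"] / small_layout.gsd - fy0
        hits = [
            sum(b.contains(c, r) for b in grown)
            for c, r in zip(cols, rows_)
        ]
        assert all(h == 1 for h in hits)

    def test_empty_band_yields_no_rows(self, segmented, small_layout):
        img, _, _, _, _, _ = segmented
        params = seg.SegmentationParams(row_length_px=400, plant_width_px=12)
        soil_band = seg.BlockBand(index=0, y0=405, y1=445, core_y0=405, core_y1=445)
        with pytest.warns(UserWarning, match="no vegetation"):
            assert seg.detect_rows(img, soil_band, params) == []
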