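"""Connected components, binarization and the recursive splitting loop."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffsplit import (
    SceneParams,
    SegmenterConfig,
    SemanticMask,
    SplitFieldPair,
    binarize_split,
    connected_components,
    generate_dataset,
    segment,
)
from diffsplit.oracle import ConstantSplitModel, OracleSplitModel
from diffsplit.diffusion import make_schedule


def bfs_components(binary):
    """Flood-fill oracle for 8-connected components."""
    binary = binary.astype(bool)
    h, w = binary.shape
    seen = np.zeros_like(binary)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                comp = np.zeros_like(binary)
                q = deque([(r, c)])
                seen[r, c] = True
                while q:
                    y, x = q.popleft()
                    comp[y, x] = True
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (
                                0 <= ny < h and 0 <= nx < w
                                and binary[ny, nx] and not seen[ny, nx]
                            ):
                                seen[ny, nx] = True
                                q.append((ny, nx))
                comps.append(comp)
    return comps


class TestConnectedComponents:
    def test_two_disjoint_blobs(self, two_blob_scene):
        cc = connected_components(two_blob_scene.semantic.binary)
        assert len(cc) == 2

    def test_border_touching_blob_is_one_component(self):
        b = np.zeros((10, 10), bool)
        b[0:3, 0:3] = True
        assert len(connected_components(b)) == 1

    def test_empty_input_empty_set(self):
        assert len(connected_components(np.zeros((8, 8), bool))) == 0

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bfs_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((32, 32)) < 0.35
        ours = connected_components(binary)
        oracle = bfs_components(binary)
        assert len(ours) == len(oracle)
        ours_sets = {m.pixels.tobytes() for m in ours}
        oracle_sets = {c.tobytes() for c in oracle}
        assert ours_sets == oracle_sets


class TestBinarizeSplit:
    def test_constant_model_extreme_case(self, overlap_scene):
        S = overlap_scene.semantic
        f = SplitFieldPair(A=S.pixels.copy(), B=np.zeros_like(S.pixels))
        sa, sb = binarize_split(f, S, 0.5)
        np.testing.assert_array_equal(sa, S.binary)
        assert not sb.any()

    def test_pixel_can_join_both_splits(self):
        s = SemanticMask(np.ones((8, 8), np.float32))
        f = SplitFieldPair(A=np.full((8, 8), 0.9, np.float32), B=np.full((8, 8), 0.8, np.float32))
        sa, sb = binarize_split(f, s, 0.5)
        assert sa.all() and sb.all()

    def test_zero_threshold_degenerate(self, overlap_scene):
        S = overlap_scene.semantic
        f = SplitFieldPair(A=np.zeros_like(S.pixels), B=np.zeros_like(S.pixels))
        sa, sb = binarize_split(f, S, 0.0)
        np.testing.assert_array_equal(sa, S.binary)
        np.testing.assert_array_equal(sb, S.binary)


class TestSegment:
    def test_disjoint_blobs_come_back_unsplit(self, two_blob_scene):
        model = ConstantSplitModel(1.0, 0.0)  # never proposes a split
        out = segment(
            model, two_blob_scene.image, two_blob_scene.semantic,
            make_schedule(3), SegmenterConfig(min_instance_pixels=3), seed=0,
        )
        assert len(out) == 2
        truth = {m.pixels.tobytes() for m in two_blob_scene.labels}
        assert {m.pixels.tobytes() for m in out} == truth

    def test_empty_foreground_empty_result(self, two_blob_scene):
        model = ConstantSplitModel(1.0, 0.0)
        empty = SemanticMask(np.zeros_like(two_blob_scene.semantic.pixels))
        out = segment(model, two_blob_scene.image, empty, make_schedule(3), seed=0)
        assert len(out) == 0

    def test_deterministic_given_seed(self, overlap_scene):
        model = OracleSplitModel(overlap_scene.labels)
        sched = make_schedule(3)
        a = segment(model, overlap_scene.image, overlap_scene.semantic, sched, seed=4)
        b = segment(model, overlap_scene.image, overlap_scene.semantic, sched, seed=4)
        assert len(a) == len(b)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.pixels, mb.pixels)

    def test_output_confined_to_foreground_and_nonempty(self, overlap_scene):
        model = OracleSplitModel(overlap_scene.labels)
        out = segment(
            model, overlap_scene.image, overlap_scene.semantic, make_schedule(3),
            SegmenterConfig(min_instance_pixels=3), seed=1,
        )
        fg = overlap_scene.semantic.binary
        for m in out:
            assert m.pixels.sum() >= 1
            assert not (m.pixels & ~fg).any()

    def test_oracle_model_recovers_overlapping_pair(self, overlap_scene):
        model = OracleSplitModel(overlap_scene.labels)
        out = segment(
            model, overlap_scene.image, overlap_scene.semantic, make_schedule(3),
            SegmenterConfig(min_instance_pixels=3), seed=0,
        )
        truth = {m.pixels.tobytes() for m in overlap_scene.labels}
        assert {m.pixels.tobytes() for m in out} == truth

    @pytest.mark.parametrize("n_cells,overlap", [(3, 0.7), (4, 0.5)])
    def test_oracle_model_recovers_multi_cell_scenes(self, n_cells, overlap):
        params = SceneParams(
            height=96, width=96, n_cells=n_cells, overlap_fraction=overlap,
            radius_range=(6.0, 9.0),
        )
        scenes = generate_dataset(params, 5, seed=31)
        sched = make_schedule(3)
        for i, sc in enumerate(scenes):
            model = OracleSplitModel(sc.labels)
            out = segment(
                model, sc.image, sc.semantic, sched,
                SegmenterConfig(min_instance_pixels=3), seed=100 + i,
            )
            truth = {m.pixels.tobytes() for m in sc.labels}
            assert {m.pixels.tobytes() for m in out} == truth

    def test_fixed_recursions_mode_runs(self, overlap_scene):
        model = OracleSplitModel(overlap_scene.labels)
        out = segment(
            model, overlap_scene.image, overlap_scene.semantic, make_schedule(3),
            SegmenterConfig(fixed_recursions=3, min_instance_pixels=3), seed=0,
        )
        truth = {m.pixels.tobytes() for m in overlap_scene.labels}
        assert {m.pixels.tobytes() for m in out} == truth

    def test_min_instance_pixels_filters_specks(self, two_blob_scene):
        model = ConstantSplitModel(1.0, 0.0)
        out = segment(
            model, two_blob_scene.image, two_blob_scene.semantic, make_schedule(3),
            SegmenterConfig(min_instance_pixels=1000), seed=0,
        )
        assert len(out) == 0
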