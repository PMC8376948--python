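"""Thresholding, blob extraction, argmax labeling and structure refinement."""

import numpy as np
import pytest

from carieseg import (
    Blob,
    DetectionResult,
    StructureLabel,
    StructureMask,
    ValidationError,
    binarize,
    extract_blobs,
    refine,
    render_overlay,
    structure_labelmap,
)
from carieseg.types import Radiograph


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """Independent brute-force connected-components oracle."""
    h, w = binary.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if binary[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = set()
                while stack:
                    y, x = stack.pop()
                    comp.add((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and binary[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(frozenset(comp))
    return comps


class TestBinarize:
    def test_exactly_at_threshold_is_negative(self):
        # "more than" the operating point is strict
        prob = np.array([[0.55, 0.551], [0.549, 0.9]])
        out = binarize(prob, 0.55)
        assert out.tolist() == [[0, 1], [0, 1]]

    def test_all_zero_map(self):
        assert not binarize(np.zeros((5, 5)), 0.55).any()

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        prob = rng.random((30, 30))
        counts = [binarize(prob, t).sum() for t in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_threshold_range(self, bad):
        with pytest.raises(ValidationError):
            binarize(np.zeros((3, 3)), bad)


class TestExtractBlobs:
    def test_diagonal_pixels_connectivity(self):
        grid = np.zeros((4, 4), dtype=np.uint8)
        grid[1, 1] = grid[2, 2] = 1
        prob = grid.astype(float)
        assert len(extract_blobs(grid, prob, connectivity=8)) == 1
        assert len(extract_blobs(grid, prob, connectivity=4)) == 2

    def test_empty_grid(self):
        assert extract_blobs(np.zeros((6, 6), dtype=np.uint8), np.zeros((6, 6))) == []

    def test_scores_are_mean_probability(self):
        grid = np.zeros((3, 3), dtype=np.uint8)
        grid[0, 0] = grid[0, 1] = 1
        prob = np.zeros((3, 3))
        prob[0, 0], prob[0, 1] = 0.6, 0.8
        (blob,) = extract_blobs(grid, prob)
        assert blob.score == pytest.approx(0.7)
        assert blob.area == 2

    def test_deterministic_ordering(self):
        grid = np.zeros((6, 6), dtype=np.uint8)
        grid[4, 4] = 1
        grid[0, 2] = 1
        grid[2, 0] = 1
        blobs = extract_blobs(grid, grid.astype(float))
        assert [b.top_left for b in blobs] == [(0, 2), (2, 0), (4, 4)]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(5)
        for _ in range(40):
            h, w = rng.integers(1, 13, size=2)
            grid = (rng.random((h, w)) < 0.4).astype(np.uint8)
            got = {b.pixel_set for b in extract_blobs(grid, grid.astype(float),
                                                      connectivity=connectivity)}
            assert got == set(flood_fill_components(grid, connectivity))


class TestStructureLabelmap:
    def test_one_hot_recovery(self):
        labels = np.random.default_rng(0).integers(0, 7, (5, 5))
        prob = np.zeros((7, 5, 5))
        for c in range(7):
            prob[c][labels == c] = 1.0
        assert np.array_equal(structure_labelmap(prob).labels, labels)

    def test_uniform_ties_fall_to_background(self):
        prob = np.full((7, 4, 4), 1 / 7)
        assert (structure_labelmap(prob).labels == 0).all()

    def test_handcrafted_argmax(self):
        prob = np.zeros((3, 3, 3))
        prob[0] = [[0.5, 0.1, 0.1], [0.3, 0.3, 0.3], [0.2, 0.2, 0.2]]
        prob[1] = [[0.3, 0.8, 0.1], [0.4, 0.3, 0.3], [0.2, 0.6, 0.2]]
        prob[2] = 1.0 - prob[0] - prob[1]
        expected = np.stack([np.argmax(prob[:, r, c]) for r in range(3)
                             for c in range(3)]).reshape(3, 3)
        assert np.array_equal(structure_labelmap(prob).labels, expected)


def _structure_with_dentin_square():
    labels = np.zeros((10, 10), dtype=np.uint8)
    labels[2:5, 2:5] = StructureLabel.DENTIN
    labels[6, 6] = StructureLabel.ENAMEL
    return StructureMask(labels=labels)


class TestRefine:
    def test_background_blob_eliminated(self):
        struct = _structure_with_dentin_square()
        blob = Blob(pixel_set=frozenset({(8, 8), (8, 9)}), score=0.9)
        surviving, eliminated = refine([blob], struct)
        assert surviving == []
        assert eliminated[0][1] == "no-enamel-dentin-overlap"

    def test_single_enamel_pixel_survives(self):
        struct = _structure_with_dentin_square()
        blob = Blob(pixel_set=frozenset({(6, 6), (8, 8), (9, 9)}), score=0.5)
        surviving, eliminated = refine([blob], struct)
        assert surviving == [blob] and eliminated == []

    def test_empty_list(self):
        assert refine([], _structure_with_dentin_square()) == ([], [])

    def test_idempotent(self):
        struct = _structure_with_dentin_square()
        blobs = [Blob(pixel_set=frozenset({(3, 3)}), score=0.8),
                 Blob(pixel_set=frozenset({(0, 0)}), score=0.7)]
        surviving, _ = refine(blobs, struct)
        again, dropped = refine(surviving, struct)
        assert again == surviving and dropped == []

    def test_pulp_and_restoration_do_not_rescue(self):
        labels = np.zeros((6, 6), dtype=np.uint8)
        labels[1, 1] = StructureLabel.PULP
        labels[2, 2] = StructureLabel.METAL_RESTORATION
        blob = Blob(pixel_set=frozenset({(1, 1), (2, 2)}), score=0.6)
        surviving, eliminated = refine([blob], StructureMask(labels=labels))
        assert surviving == [] and len(eliminated) == 1


class TestRenderOverlay:
    def test_summary_bookkeeping_and_pixel_union(self):
        rad = Radiograph(pixels=np.full((32, 32), 2000, dtype=np.uint16), id="x")
        blob = Blob(pixel_set=frozenset({(1, 1), (1, 2), (2, 1), (2, 2),
                                         (3, 1), (3, 2), (4, 1)}), score=0.8)
        result = DetectionResult(radiograph_id="x", threshold=0.55, surviving=[blob])
        rgb, summary = render_overlay(rad, result)
        assert summary == [{"blob": 0, "area_px": 7, "mean_prob": 0.8}]
        marked = {tuple(p) for p in np.argwhere(rgb[:, :, 0] == 255)}
        assert marked == set(blob.pixel_set)

    def test_zero_blobs_leaves_image_gray(self):
        rad = Radiograph(pixels=np.full((32, 32), 1000, dtype=np.uint16), id="x")
        result = DetectionResult(radiograph_id="x", threshold=0.55)
        rgb, summary = render_overlay(rad, result)
        assert summary == []
        assert (rgb[:, :, 0] == rgb[:, :, 1]).all() and (rgb[:, :, 1] == rgb[:, :, 2]).all()
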