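"""Edge extraction, morphology, labeling and counting tests."""

import numpy as np
import pytest

from _oracles import flood_fill_label, reachable_from_border
from milkscc import (
    ConfigError,
    SegmentConfig,
    auto_canny_thresholds,
    canny_edges,
    count_cells,
    count_pipeline,
    label_components,
    morphological_open,
)
from milkscc.synthetic import generate_cavity


def disk_mask(shape, center, radius):
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def ring(shape, center, radius):
    return disk_mask(shape, center, radius) & ~disk_mask(shape, center, radius - 2)


class TestAutoThresholds:
    def test_closed_form_on_constant_image(self):
        img = np.full((10, 10), 100, dtype=np.uint8)
        assert auto_canny_thresholds(img, 0.33) == (67, 133)

    def test_degenerate_zero_image_falls_back(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        assert auto_canny_thresholds(img, 0.33) == (0, 0)
        # the edge detector falls back to fixed thresholds and finds nothing
        assert canny_edges(img).sum() == 0

    def test_matches_formula_on_noise(self, rng):
        img = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        med = float(np.median(img))
        low, high = auto_canny_thresholds(img, 0.4)
        assert low == int(max(0.0, 0.6 * med)) and high == int(min(255.0, 1.4 * med))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ConfigError):
            auto_canny_thresholds(np.zeros((5, 5), dtype=np.uint8), 1.5)


class TestCannyEdges:
    def test_constant_image_has_no_edges(self):
        assert canny_edges(np.full((20, 20), 77, dtype=np.uint8)).sum() == 0

    def test_disk_yields_closed_ring(self):
        img = np.full((40, 40), 20, dtype=np.uint8)
        img[disk_mask((40, 40), (20, 20), 10)] = 200
        edges = canny_edges(img, SegmentConfig(canny_low=50, canny_high=150))
        assert edges.dtype == bool and edges.any()
        # the ring encloses the centre: outside flood fill cannot reach it
        assert not reachable_from_border(edges)[20, 20]

    def test_step_edge_localised(self):
        img = np.zeros((30, 30), dtype=np.uint8)
        img[:, 15:] = 200
        edges = canny_edges(img, SegmentConfig(canny_low=50, canny_high=150))
        cols = np.where(edges.any(axis=0))[0]
        assert cols.size > 0 and cols.max() - cols.min() <= 1

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            SegmentConfig(canny_low=150, canny_high=50)


class TestMorphologicalOpen:
    def test_isolated_pixel_removed(self):
        img = np.zeros((9, 9), dtype=bool)
        img[4, 4] = True
        out = morphological_open(img, SegmentConfig(open_size=1))
        assert out.sum() == 0

    def test_solid_square_unchanged(self):
        img = np.zeros((14, 14), dtype=bool)
        img[2:12, 2:12] = True
        out = morphological_open(img, SegmentConfig(open_size=1))
        assert np.array_equal(out, img)

    def test_idempotent(self, rng):
        img = rng.random((32, 32)) < 0.4
        cfg = SegmentConfig(open_size=1)
        once = morphological_open(img, cfg)
        assert np.array_equal(morphological_open(once, cfg), once)

    def test_never_adds_foreground(self, rng):
        for shape in ("square", "ellipse"):
            img = rng.random((24, 24)) < 0.5
            out = morphological_open(img, SegmentConfig(open_size=1, open_shape=shape))
            assert out.sum() <= img.sum()
            assert not (out & ~img).any()

    def test_default_unit_element_is_identity(self, rng):
        img = rng.random((16, 16)) < 0.3
        assert np.array_equal(morphological_open(img), img)


class TestLabelComponents:
    def test_blank_image_has_no_components(self):
        assert len(label_components(np.zeros((8, 8), dtype=bool))) == 0

    def test_two_separated_squares(self):
        img = np.zeros((10, 12), dtype=bool)
        img[2:5, 1:4] = True
        img[2:5, 7:10] = True
        comps = label_components(img, 8)
        assert len(comps) == 2
        assert sorted(c.pixel_count for c in comps.components) == [9, 9]

    def test_diagonal_pair_connectivity(self):
        img = np.zeros((4, 4), dtype=bool)
        img[1, 1] = img[2, 2] = True
        assert len(label_components(img, 8)) == 1
        assert len(label_components(img, 4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        """200 seeded random binary rasters, checked label-by-label."""
        rng = np.random.default_rng(connectivity)
        for _ in range(200):
            img = rng.random((16, 16)) < rng.uniform(0.2, 0.7)
            ours = label_components(img, connectivity)
            oracle = flood_fill_label(img, connectivity)
            assert len(ours) == oracle.max()
            # identical partitions: every label pair maps one-to-one
            both = np.stack([ours.labels.ravel(), oracle.ravel()])
            pairs = np.unique(both[:, both[0] > 0], axis=1)
            assert pairs.shape[1] == oracle.max()


class TestCountCells:
    def test_blank_counts_zero(self):
        assert count_cells(np.zeros((20, 20), dtype=bool)).count == 0

    def test_five_rings_counted(self):
        img = np.zeros((30, 150), dtype=bool)
        for i in range(5):
            img |= ring((30, 150), (15, 15 + 30 * i), 8)
        res = count_cells(img, SegmentConfig(min_component_px=4))
        assert res.count == 5

    def test_border_touching_excluded_when_configured(self):
        img = np.zeros((40, 120), dtype=bool)
        img |= ring((40, 120), (20, 20), 8)
        img |= ring((40, 120), (20, 60), 8)
        img |= ring((40, 120), (20, 100), 8)
        img |= ring((40, 120), (0, 40), 6)  # clipped at top border
        img |= ring((40, 120), (39, 80), 6)  # clipped at bottom border
        assert count_cells(img, SegmentConfig(min_component_px=4)).count == 5
        res = count_cells(img, SegmentConfig(min_component_px=4, count_border_touching=False))
        assert res.count == 3

    def test_monotone_in_min_component_px(self, rng):
        img = rng.random((40, 40)) < 0.35
        counts = [
            count_cells(img, SegmentConfig(min_component_px=t)).count for t in (0, 5, 10, 20)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCountPipeline:
    def test_blank_noisy_cavity_counts_zero(self):
        scene = generate_cavity(0, dims=(240, 320), seed=3)
        assert count_pipeline(scene.image).count == 0

    def test_recovers_known_count_within_3_percent(self):
        scene = generate_cavity(150, dims=(480, 640), seed=11)
        res = count_pipeline(scene.image)
        assert abs(res.count - 150) / 150 <= 0.03

    def test_deterministic(self):
        scene = generate_cavity(40, dims=(240, 320), seed=5)
        a = count_pipeline(scene.image)
        b = count_pipeline(scene.image)
        assert a.count == b.count
        assert np.array_equal(a.components.labels, b.components.labels)

    def test_opening_never_increases_count_on_specks(self, rng):
        """Opening with a real element only removes specks on sparse noise."""
        img = rng.random((60, 60)) < 0.02
        before = count_cells(img, SegmentConfig(min_component_px=1)).count
        opened = morphological_open(img, SegmentConfig(open_size=1))
        after = count_cells(opened, SegmentConfig(min_component_px=1)).count
        assert after <= before
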