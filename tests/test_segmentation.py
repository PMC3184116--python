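"""Seeded region growing, background detection and section classification."""

import numpy as np
import pytest

import infarctsize as iz
from infarctsize import Label

from helpers import dice, jaccard, region_grow_reference


def _rgb(h, w, color):
    return np.full((h, w, 3), color, np.uint8)


class TestRegionGrow:
    def test_uniform_image_fills_everything(self):
        img = _rgb(20, 20, (100, 100, 100))
        mask = iz.region_grow(img, [(5, 5)], tolerance=1.0)
        assert mask.all()

    def test_stops_at_strong_colour_boundary(self):
        img = _rgb(20, 20, (255, 0, 0))
        img[:, 10:] = (0, 0, 255)
        mask = iz.region_grow(img, [(3, 3)], tolerance=50.0)
        expected = np.zeros((20, 20), bool)
        expected[:, :10] = True
        assert np.array_equal(mask, expected)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(iz.ValidationError):
            iz.region_grow(_rgb(20, 20, (0, 0, 0)), [], tolerance=10)

    def test_seed_in_forbidden_region_rejected(self):
        forbidden = np.zeros((20, 20), bool)
        forbidden[5, 5] = True
        with pytest.raises(iz.ValidationError):
            iz.region_grow(_rgb(20, 20, (0, 0, 0)), [(5, 5)], 10, forbidden=forbidden)

    def test_seed_outside_image_rejected(self):
        with pytest.raises(iz.ValidationError):
            iz.region_grow(_rgb(20, 20, (0, 0, 0)), [(25, 5)], 10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_pure_python_oracle_exactly(self, seed, connectivity):
        """The numba kernel and a plain-Python reimplementation of the same
        defined expansion order must agree pixel for pixel."""
        rng = np.random.default_rng(100 + seed)
        h, w = rng.integers(16, 33, 2)
        img = rng.integers(0, 256, (h, w, 3), dtype=np.uint8)
        forbidden = rng.random((h, w)) < 0.1
        free = np.argwhere(~forbidden)
        seeds = [tuple(free[i]) for i in rng.integers(0, len(free), 3)]
        tol = float(rng.uniform(10, 200))
        got = iz.region_grow(img, seeds, tol, forbidden=forbidden,
                             connectivity=connectivity)
        want = region_grow_reference(img, seeds, tol, forbidden=forbidden,
                                     connectivity=connectivity)
        assert np.array_equal(got, want)

    def test_monotone_in_tolerance_on_phantom(self, small_phantom):
        """Growing with a larger tolerance never loses pixels on images with
        well-separated class colours."""
        image, _, seeds = small_phantom
        previous = None
        for tol in [10.0, 30.0, 60.0, 150.0, 400.0]:
            mask = iz.region_grow(image, seeds.viable_seeds, tol)
            if previous is not None:
                assert (previous <= mask).all()
            previous = mask

    def test_deterministic(self, small_phantom):
        image, _, seeds = small_phantom
        a = iz.region_grow(image, seeds.viable_seeds, 60.0)
        b = iz.region_grow(image, seeds.viable_seeds, 60.0)
        assert np.array_equal(a, b)

    def test_recovers_viable_region(self, small_phantom):
        image, truth, seeds = small_phantom
        grown = iz.region_grow(image.pixels, seeds.viable_seeds, 60.0)
        assert dice(grown, truth.mask.mask(Label.VIABLE)) >= 0.95


class TestDetectBackground:
    def test_all_white_is_all_background(self):
        assert iz.detect_background(_rgb(32, 32, (255, 255, 255))).all()

    def test_solid_disc_is_excluded_exactly(self):
        img = _rgb(64, 64, (255, 255, 255))
        rows, cols = np.mgrid[0:64, 0:64]
        disc = np.hypot(rows - 32, cols - 32) <= 15
        img[disc] = (200, 30, 30)
        assert np.array_equal(iz.detect_background(img), ~disc)

    def test_all_tissue_image_has_no_background(self):
        assert not iz.detect_background(_rgb(32, 32, (170, 60, 70))).any()

    def test_enclosed_pale_region_is_not_background(self):
        img = _rgb(64, 64, (255, 255, 255))
        rows, cols = np.mgrid[0:64, 0:64]
        r = np.hypot(rows - 32, cols - 32)
        img[(r >= 10) & (r <= 20)] = (170, 60, 70)  # annular wall
        bg = iz.detect_background(img)
        assert not bg[32, 32]  # lumen is enclosed
        assert bg[0, 0]

    def test_phantom_background_jaccard(self, quarter_phantom):
        image, truth, _ = quarter_phantom
        got = iz.detect_background(image)
        assert jaccard(got, truth.mask.mask(Label.BACKGROUND)) >= 0.99


class TestSegmentSection:
    def test_all_white_no_seeds_is_all_background(self):
        image = iz.SectionImage(_rgb(32, 32, (255, 255, 255)), "blank")
        mask = iz.segment_section(image)
        assert (mask.labels == int(Label.BACKGROUND)).all()

    def test_labels_partition_the_image(self, quarter_segmented, quarter_phantom):
        mask, _ = quarter_segmented
        h, w = quarter_phantom[0].shape
        assert sum(mask.counts().values()) == h * w

    def test_seeds_keep_their_own_label(self, quarter_segmented, quarter_phantom):
        mask, _ = quarter_segmented
        _, _, seeds = quarter_phantom
        for r, c in seeds.lumen_seeds:
            assert mask.labels[r, c] == int(Label.LUMEN)
        for r, c in seeds.viable_seeds:
            assert mask.labels[r, c] == int(Label.VIABLE)

    def test_scar_recovered_from_phantom(self, quarter_segmented, quarter_phantom):
        mask, _ = quarter_segmented
        truth = quarter_phantom[1]
        assert dice(mask.mask(Label.INFARCT), truth.mask.mask(Label.INFARCT)) >= 0.95

    def test_healthy_phantom_has_almost_no_infarct(self):
        spec = iz.PhantomSpec(image_size=(256, 256), endo_radius=75, epi_radius=90,
                              rng_seed=5)
        image, truth, seeds = iz.render_phantom(spec)
        mask = iz.segment_section(image, seeds)
        counts = mask.counts()
        wall = counts[Label.VIABLE] + counts[Label.INFARCT]
        assert counts[Label.INFARCT] <= 0.01 * wall

    def test_bit_identical_across_runs(self, small_phantom):
        image, _, seeds = small_phantom
        a = iz.segment_section(image, seeds)
        b = iz.segment_section(image, seeds)
        assert np.array_equal(a.labels, b.labels)

    def test_tolerance_override_wins(self, small_phantom):
        image, _, seeds = small_phantom
        override = iz.SeedSet(
            lumen_seeds=seeds.lumen_seeds,
            viable_seeds=seeds.viable_seeds,
            tolerance_override=42.0,
        )
        mask = iz.segment_section(image, override, tolerance=60.0)
        assert mask.tolerance_used == 42.0


class TestExclusion:
    def test_polygon_over_whole_image_excludes_everything(self):
        mask = iz.LabelMask(np.full((32, 32), int(Label.VIABLE), np.uint8))
        out = iz.apply_exclusion(mask, [(-1, -1), (-1, 40), (40, 40), (40, -1)])
        assert (out.labels == int(Label.EXCLUDED)).all()

    def test_polygon_in_background_changes_no_tissue_counts(self, quarter_segmented):
        mask, _ = quarter_segmented
        out = iz.apply_exclusion(mask, [(2, 2), (2, 12), (12, 12), (12, 2)])
        before, after = mask.counts(), out.counts()
        for lab in (Label.LUMEN, Label.VIABLE, Label.INFARCT):
            assert after[lab] == before[lab]

    def test_idempotent(self, quarter_segmented):
        mask, _ = quarter_segmented
        poly = [(10, 10), (10, 60), (60, 60)]
        once = iz.apply_exclusion(mask, poly)
        twice = iz.apply_exclusion(once, poly)
        assert np.array_equal(once.labels, twice.labels)

    def test_degenerate_polygon_rejected(self, quarter_segmented):
        mask, _ = quarter_segmented
        with pytest.raises(iz.ValidationError):
            iz.apply_exclusion(mask, [(0, 0), (5, 5)])

    def test_excluding_decoy_blob_restores_clean_score(self):
        """A decoy right-ventricle blob inflates the residual scar class;
        excluding it must restore the clean phantom's area score."""
        base = dict(image_size=(256, 256), endo_radius=75.0, epi_radius=90.0,
                    infarct_sector=(0.0, np.pi / 2), rng_seed=21)
        clean_spec = iz.PhantomSpec(**base)
        blob_spec = iz.PhantomSpec(**base, decoy_blob=((40.0, 40.0), 18.0))
        clean_img, _, seeds = iz.render_phantom(clean_spec)
        blob_img, _, blob_seeds = iz.render_phantom(blob_spec)

        clean_area = iz.area_score(iz.segment_section(clean_img, seeds))
        blob_mask = iz.segment_section(blob_img, blob_seeds)
        inflated = iz.area_score(blob_mask)
        fixed = iz.area_score(
            iz.apply_exclusion(blob_mask, [(15, 15), (15, 65), (65, 65), (65, 15)])
        )
        assert inflated > clean_area + 0.5
        assert abs(fixed - clean_area) <= 0.5
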