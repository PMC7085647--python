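"""Connected-component morphometrics and the two noise filters."""

import numpy as np
import pytest

from floralquant import (
    ComponentRecord,
    MorphologyLimits,
    component_properties,
    denoise,
    denoise_report,
    filter_by_canopy_adjacency,
    filter_by_morphology,
    label_components,
    segment_canopy,
    segment_flower_candidates,
)
from floralquant.noise import moment_ellipse_axes, touches_canopy


def brute_force_axes(coords):
    """Second central moments by explicit summation; axes = 4 sqrt(eigenvalues)."""
    coords = np.asarray(coords, float)
    n = len(coords)
    rbar, cbar = coords.mean(axis=0)
    mu20 = sum((r - rbar) ** 2 for r, c in coords) / n
    mu02 = sum((c - cbar) ** 2 for r, c in coords) / n
    mu11 = sum((r - rbar) * (c - cbar) for r, c in coords) / n
    tr, det = mu20 + mu02, mu20 * mu02 - mu11**2
    disc = max(tr * tr / 4 - det, 0.0)
    l1 = tr / 2 + disc**0.5
    l2 = tr / 2 - disc**0.5
    return 4 * l1**0.5, 4 * max(l2, 0.0) ** 0.5


def brute_force_adjacency_keep(component_pixels, canopy):
    """Enumerate every pixel's 8-neighborhood and test canopy membership."""
    comp = set(map(tuple, component_pixels))
    h, w = canopy.shape
    for r, c in comp:
        if canopy[r, c]:
            return True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (rr, cc) in comp or not (0 <= rr < h and 0 <= cc < w):
                    continue
                if canopy[rr, cc]:
                    return True
    return False


class TestLabeling:
    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        comps = label_components(mask)
        assert sorted(c.area_px for c in comps) == [9, 9]

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=8)) == 1
        assert len(label_components(mask, connectivity=4)) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), bool)) == []

    def test_every_true_pixel_in_exactly_one_component(self):
        rng = np.random.default_rng(5)
        mask = rng.random((32, 32)) < 0.4
        comps = label_components(mask)
        total = sum(c.area_px for c in comps)
        assert total == int(mask.sum())
        seen = set()
        for c in comps:
            for rc in map(tuple, c.coords):
                assert rc not in seen
                seen.add(rc)


class TestComponentProperties:
    def test_filled_square_is_round_and_solid(self):
        coords = np.argwhere(np.ones((10, 10), bool))
        rec = component_properties(ComponentRecord(1, coords))
        assert rec.area_px == 100
        assert rec.axis_ratio == pytest.approx(1.0, abs=1e-6)
        assert rec.solidity == pytest.approx(1.0)

    def test_line_axis_ratio_matches_moment_oracle(self):
        coords = np.array([(0, c) for c in range(20)])
        rec = component_properties(ComponentRecord(1, coords))
        want_major, want_minor = brute_force_axes(coords)
        got_major, got_minor = moment_ellipse_axes(coords)
        assert got_major == pytest.approx(want_major, abs=1e-9)
        assert got_minor == pytest.approx(want_minor, abs=1e-9)
        assert rec.axis_ratio > 5  # collinear -> infinitely elongated here

    def test_axes_match_oracle_on_random_blobs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            coords = np.unique(rng.integers(0, 12, size=(30, 2)), axis=0)
            got = moment_ellipse_axes(coords)
            want = brute_force_axes(coords)
            assert np.allclose(got, want, atol=1e-9)

    def test_axes_match_skimage_regionprops(self):
        """Cross-check the moment ellipse against an independent implementation."""
        from skimage import measure

        rng = np.random.default_rng(3)
        mask = rng.random((24, 24)) < 0.45
        for p in measure.regionprops(measure.label(mask, connectivity=2)):
            if p.area < 3:
                continue
            major, minor = moment_ellipse_axes(p.coords)
            assert major == pytest.approx(p.axis_major_length, abs=1e-7)
            assert minor == pytest.approx(p.axis_minor_length, abs=1e-7)

    def test_plus_shape_not_fully_solid(self):
        mask = np.zeros((5, 5), bool)
        mask[2, :] = mask[:, 2] = True  # 9-px cross; hull fills the corners
        rec = component_properties(ComponentRecord(1, np.argwhere(mask)))
        assert 0 < rec.solidity < 1.0

    def test_single_pixel_degenerate_convention(self):
        rec = component_properties(ComponentRecord(1, np.array([(3, 3)])))
        assert rec.axis_ratio == 1.0 and rec.solidity == 1.0


class TestMorphologyFilter:
    def test_straw_line_removed_blob_kept(self):
        mask = np.zeros((30, 40), bool)
        mask[2, 5:30] = True  # elongated straw
        rr, cc = np.mgrid[15:25, 15:25]
        keep = (rr - 19.5) ** 2 + (cc - 19.5) ** 2 <= 20
        mask[rr[keep], cc[keep]] = True  # round flower blob
        comps = label_components(mask)
        limits = MorphologyLimits(
            min_area_px=5, max_area_px=1000, max_axis_ratio=4.0, min_solidity=0.6
        )
        out = filter_by_morphology(comps, limits, mask.shape)
        assert not out[2, 5:30].any()
        assert out[rr[keep], cc[keep]].all()

    def test_identity_limits_keep_everything(self):
        rng = np.random.default_rng(7)
        mask = rng.random((20, 20)) < 0.3
        limits = MorphologyLimits(
            min_area_px=1, max_area_px=10**9, max_axis_ratio=float("inf"), min_solidity=1e-12
        )
        out = filter_by_morphology(label_components(mask), limits, mask.shape)
        assert np.array_equal(out, mask)

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError):
            MorphologyLimits(min_area_px=10, max_area_px=5)
        with pytest.raises(ValueError):
            MorphologyLimits(min_solidity=0.0)


class TestCanopyAdjacency:
    def _canopy(self):
        canopy = np.zeros((20, 20), bool)
        canopy[:, :8] = True
        return canopy

    def test_blob_touching_canopy_kept(self):
        canopy = self._canopy()
        cand = np.zeros_like(canopy)
        cand[5:8, 8:11] = True  # ring reaches column 7 = canopy
        out = filter_by_canopy_adjacency(label_components(cand), canopy)
        assert np.array_equal(out, cand)

    def test_isolated_blob_removed(self):
        canopy = self._canopy()
        cand = np.zeros_like(canopy)
        cand[5:8, 12:15] = True  # >= 2 px from canopy
        out = filter_by_canopy_adjacency(label_components(cand), canopy)
        assert not out.any()

    def test_blob_inside_canopy_kept(self):
        canopy = self._canopy()
        cand = np.zeros_like(canopy)
        cand[3:6, 2:5] = True
        out = filter_by_canopy_adjacency(label_components(cand), canopy)
        assert np.array_equal(out, cand)

    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            cand = rng.random((32, 32)) < 0.25
            canopy = rng.random((32, 32)) < 0.3
            comps = label_components(cand)
            got = filter_by_canopy_adjacency(comps, canopy)
            want = np.zeros_like(cand)
            for c in comps:
                if brute_force_adjacency_keep(c.coords, canopy):
                    want[c.coords[:, 0], c.coords[:, 1]] = True
            assert np.array_equal(got, want)

    def test_wider_ring_reaches_farther(self):
        canopy = self._canopy()
        cand = np.zeros_like(canopy)
        cand[5:8, 9:12] = True  # 1 px soil gap: ring 1 misses, ring 2 reaches
        comps = label_components(cand)
        assert not touches_canopy(comps[0], canopy, ring_width=1)
        assert touches_canopy(comps[0], canopy, ring_width=2)


class TestDenoise:
    def test_scene_composition_recovers_exactly_the_flowers(
        self, noisy_pea_scene, pea_profile
    ):
        img, truth = noisy_pea_scene
        canopy = segment_canopy(img, pea_profile)
        cand = segment_flower_candidates(img, pea_profile)
        assert truth.straw_mask.sum() > 0 and truth.glint_mask.sum() > 0
        out, report = denoise_report(cand, canopy, pea_profile.morphology)
        assert np.array_equal(out, truth.flower_mask)
        dropped = report[~report.kept]
        assert set(dropped.drop_reason) <= {"min_area", "max_area", "axis_ratio",
                                            "solidity", "no_canopy_neighbor"}
        assert len(report[report.kept]) == len(truth.flowers)

    def test_output_is_subset_of_candidates(self):
        rng = np.random.default_rng(9)
        cand = rng.random((40, 40)) < 0.2
        canopy = rng.random((40, 40)) < 0.3
        out = denoise(cand, canopy)
        assert not (out & ~cand).any()

    def test_filter_order_does_not_matter(self):
        rng = np.random.default_rng(13)
        limits = MorphologyLimits(min_area_px=2, max_axis_ratio=6.0, min_solidity=0.3)
        for _ in range(10):
            cand = rng.random((32, 32)) < 0.25
            canopy = rng.random((32, 32)) < 0.3
            comps = label_components(cand)
            m_then_a = filter_by_canopy_adjacency(
                label_components(filter_by_morphology(comps, limits, cand.shape)), canopy
            )
            a_then_m = filter_by_morphology(
                label_components(filter_by_canopy_adjacency(comps, canopy)), limits, cand.shape
            )
            assert np.array_equal(m_then_a, a_then_m)

    def test_all_noise_gives_empty_mask(self, pea_profile):
        cand = np.zeros((20, 20), bool)
        cand[2, 2:18] = True  # one long straw line
        canopy = np.zeros_like(cand)
        canopy[15:, :] = True
        assert not denoise(cand, canopy, pea_profile.morphology).any()

    def test_no_canopy_anywhere_removes_everything(self):
        cand = np.zeros((20, 20), bool)
        cand[5:9, 5:9] = True
        assert not denoise(cand, np.zeros_like(cand)).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            denoise(np.zeros((4, 4), bool), np.zeros((5, 5), bool))
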