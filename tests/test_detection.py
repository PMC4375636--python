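"""Boundary marking, margin filtering, region growing and the full pipeline."""

import numpy as np
import pytest

from wmidetect import (
    BoundarySet,
    DetectionConfig,
    TransitionModel,
    detect,
    grow_regions,
    mark_boundaries,
    remove_margin_false_boundaries,
    stretch_and_quantize,
)
from wmidetect.transition import NEIGHBOR_OFFSETS

from conftest import make_state_image


def brute_force_boundaries(states, mask, model, threshold):
    """All-pairs oracle for rare-transition marking."""
    rows, cols = states.shape
    pixels, seeds = set(), set()
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in NEIGHBOR_OFFSETS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]):
                    continue
                drop = abs(int(states[r, c]) - int(states[rr, cc]))
                if model.probs[drop] < threshold:
                    pixels.add((r, c))
                    pixels.add((rr, cc))
                    if states[r, c] > states[rr, cc]:
                        seeds.add((r, c))
                    elif states[rr, cc] > states[r, c]:
                        seeds.add((rr, cc))
    return pixels, seeds


class TestMarkBoundaries:
    def test_uniform_image_empty(self):
        si = make_state_image(np.full((6, 6), 3), n_states=4)
        model = TransitionModel.from_q(0.8, 3)
        b = mark_boundaries(si, model, DetectionConfig())
        assert len(b.pixels) == 0 and len(b.seeds) == 0

    def test_worked_example_pair(self):
        # with q=0.8, n=3 only the 3 -> 0 transition is rarer than 1%
        si = make_state_image(np.array([[3, 0]]), n_states=4)
        model = TransitionModel.from_q(0.8, 3)
        b = mark_boundaries(si, model, DetectionConfig(threshold=0.01))
        assert b.pixels == {(0, 0), (0, 1)}
        assert b.seeds == {(0, 0)}  # the brighter pixel seeds growth

    def test_subthreshold_drop_not_marked(self):
        si = make_state_image(np.array([[2, 0]]), n_states=4)
        model = TransitionModel.from_q(0.8, 3)
        b = mark_boundaries(si, model, DetectionConfig(threshold=0.01))
        assert len(b.pixels) == 0

    def test_matches_exhaustive_oracle(self, rng):
        model = TransitionModel.from_q(0.8, 6)
        cfg = DetectionConfig(threshold=0.01)
        for _ in range(30):
            states = rng.integers(0, 7, size=(16, 16))
            mask = rng.random((16, 16)) < 0.85
            states[~mask] = -1
            si = make_state_image(np.where(mask, states, -1), n_states=7)
            b = mark_boundaries(si, model, cfg)
            pixels, seeds = brute_force_boundaries(states, mask, model, cfg.threshold)
            assert set(b.pixels) == pixels
            assert set(b.seeds) == seeds

    def test_threshold_monotonicity(self, rng):
        model = TransitionModel.from_q(0.7, 6)
        states = rng.integers(0, 7, size=(20, 20))
        si = make_state_image(states, n_states=7)
        prev = None
        for thr in (0.002, 0.01, 0.05, 0.2):
            b = mark_boundaries(si, model, DetectionConfig(threshold=thr))
            if prev is not None:
                assert prev <= b.pixels  # lowering the threshold never adds
            prev = b.pixels

    def test_state_space_mismatch(self):
        si = make_state_image(np.array([[3, 0]]), n_states=4)
        model = TransitionModel.from_q(0.8, 6)
        with pytest.raises(ValueError, match="mismatch"):
            mark_boundaries(si, model, DetectionConfig())


class TestRemoveMarginFalseBoundaries:
    def test_border_pixels_removed(self):
        mask = np.ones((10, 10), dtype=bool)
        border = {(0, c) for c in range(10)}
        b = BoundarySet(frozenset(border), frozenset())
        out = remove_margin_false_boundaries(b, mask, DetectionConfig(margin_px=2))
        assert len(out.pixels) == 0

    def test_small_components_removed(self):
        mask = np.ones((20, 20), dtype=bool)
        big = {(10, c) for c in range(5, 10)}  # 5-pixel line at center
        small = {(15, 5), (15, 6)}  # 2-pixel component
        b = BoundarySet(frozenset(big | small), frozenset({(10, 5), (15, 5)}))
        out = remove_margin_false_boundaries(
            b, mask, DetectionConfig(margin_px=2, min_boundary_px=3)
        )
        assert out.pixels == big
        assert out.seeds == {(10, 5)}  # seed filtered with its pixel

    def test_empty_identity(self):
        out = remove_margin_false_boundaries(
            BoundarySet.empty(), np.ones((5, 5), dtype=bool), DetectionConfig()
        )
        assert len(out.pixels) == 0

    def test_margin_zero_keeps_interior_border(self):
        mask = np.ones((10, 10), dtype=bool)
        b = BoundarySet(frozenset({(5, j) for j in range(3, 8)}), frozenset())
        out = remove_margin_false_boundaries(b, mask, DetectionConfig(margin_px=0))
        assert out.pixels == b.pixels


class TestGrowRegions:
    @staticmethod
    def disc_scene():
        """Uniform bright disc (1.0) on background 0.2, full mask."""
        image = np.full((21, 21), 0.2)
        rr, cc = np.mgrid[0:21, 0:21]
        disc = np.hypot(rr - 10, cc - 10) <= 4
        image[disc] = 1.0
        mask = np.ones((21, 21), dtype=bool)
        si = stretch_and_quantize(image, mask, n_states=7, clip_percentiles=(0, 100))
        return image, mask, disc, si

    def test_uniform_disc_grows_exactly(self):
        image, mask, disc, si = self.disc_scene()
        seed = (10, 10)
        b = BoundarySet(frozenset({seed}), frozenset({seed}))
        cfg = DetectionConfig(growth_fraction=0.5, max_region_px=1000)
        lm = grow_regions(si.stretched, b, mask, cfg, si)
        # sd inside the disc is 0, so growth proceeds by exact state match
        assert np.array_equal(lm.mask, disc)
        assert not lm.capped

    def test_growth_fraction_zero_seeds_only(self):
        image, mask, disc, si = self.disc_scene()
        seeds = {(10, 10), (9, 9)}
        b = BoundarySet(frozenset(seeds), frozenset(seeds))
        lm = grow_regions(si.stretched, b, mask, DetectionConfig(growth_fraction=0.0), si)
        assert {tuple(p) for p in np.argwhere(lm.mask)} == seeds

    def test_two_seeds_one_component(self):
        image, mask, disc, si = self.disc_scene()
        seeds = {(10, 10), (8, 12)}
        b = BoundarySet(frozenset(seeds), frozenset(seeds))
        lm = grow_regions(si.stretched, b, mask, DetectionConfig(), si)
        assert lm.n_components == 1

    def test_empty_seed_set(self):
        image, mask, disc, si = self.disc_scene()
        lm = grow_regions(si.stretched, BoundarySet.empty(), mask, DetectionConfig(), si)
        assert lm.area_px == 0 and lm.n_components == 0

    def test_region_cap_reported(self):
        image, mask, disc, si = self.disc_scene()
        seed = (10, 10)
        b = BoundarySet(frozenset({seed}), frozenset({seed}))
        lm = grow_regions(
            si.stretched, b, mask, DetectionConfig(max_region_px=5), si
        )
        assert lm.capped
        assert lm.area_px == 5

    def test_component_bookkeeping(self):
        image, mask, disc, si = self.disc_scene()
        seed = (10, 10)
        b = BoundarySet(frozenset({seed}), frozenset({seed}))
        lm = grow_regions(si.stretched, b, mask, DetectionConfig(), si)
        assert sum(a for _, a, _ in lm.per_component) == lm.area_px
        assert lm.labels.max() == lm.n_components


class TestDetectPipeline:
    def test_lesioned_phantom_detected(self, lesioned_phantom):
        image, wm, truth, manifest = lesioned_phantom
        lesions, report = detect(image, wm)
        assert lesions.n_components >= 1
        assert (lesions.mask & truth).any()
        assert report["q_source"] == "estimated"
        assert 0.0 < report["q"] < 1.0

    def test_clean_phantom_empty(self, clean_phantom):
        image, wm, truth, _ = clean_phantom
        lesions, _ = detect(image, wm)
        assert lesions.area_px == 0

    def test_lesion_mask_within_wm(self, lesioned_phantom):
        image, wm, _, _ = lesioned_phantom
        lesions, _ = detect(image, wm)
        assert not (lesions.mask & ~wm).any()

    def test_deterministic(self, lesioned_phantom):
        image, wm, _, _ = lesioned_phantom
        a, ra = detect(image, wm)
        b, rb = detect(image, wm)
        assert np.array_equal(a.mask, b.mask)
        assert ra == rb

    def test_fixed_q_pipeline(self, lesioned_phantom):
        image, wm, truth, _ = lesioned_phantom
        lesions, report = detect(image, wm, q=0.8)
        assert report["q"] == 0.8 and report["q_source"] == "fixed"
        assert (lesions.mask & truth).any()

    def test_report_embeds_config(self, lesioned_phantom):
        image, wm, _, _ = lesioned_phantom
        cfg = DetectionConfig(threshold=0.02, margin_px=3)
        _, report = detect(image, wm, cfg=cfg)
        assert report["config"]["threshold"] == 0.02
        assert report["config"]["margin_px"] == 3

    def test_bright_rim_false_positives_removed_by_margin(self):
        from wmidetect import PhantomSpec, generate

        image, wm, truth, _ = generate(PhantomSpec(seed=5, rim_width=2))
        with_rim, _ = detect(image, wm, cfg=DetectionConfig(margin_px=0))
        cleaned, _ = detect(image, wm, cfg=DetectionConfig(margin_px=2))
        assert with_rim.n_components > 0  # grey-matter rim mimics injury
        assert cleaned.area_px == 0


def test_config_validation():
    with pytest.raises(ValueError):
        DetectionConfig(threshold=0.0)
    with pytest.raises(ValueError):
        DetectionConfig(margin_px=-1)
    with pytest.raises(ValueError):
        DetectionConfig(min_boundary_px=0)
    with pytest.raises(ValueError):
        DetectionConfig(growth_fraction=-0.1)
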