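"""Rare-transition boundary marking, margin filtering, and region growing.

Detection proceeds in three stages over a quantized slice:

1. every 8-connected in-mask pixel pair whose state drop has conditional
   probability below a threshold is marked as a potential lesion boundary,
   with the brighter pixel of each pair recorded as a growth seed;
2. boundary pixels inside a band around the white-matter margin are
   discarded (partial-volume transitions to grey matter mimic lesions
   there), and boundary components too small to be credible are dropped;
3. lesions are grown from the surviving seeds by breadth-first accretion of
   neighbours whose intensity sits within a fraction of a standard
   deviation of the running region mean.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .quantize import StateImage, stretch_and_quantize
from .transition import (
    NEIGHBOR_OFFSETS,
    TransitionModel,
    estimate_q,
    _shifted_views,
)

__all__ = [
    "DetectionConfig",
    "BoundarySet",
    "LesionMask",
    "mark_boundaries",
    "remove_margin_false_boundaries",
    "grow_regions",
    "calibrate_threshold",
    "detect",
]

EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable knobs of the detector.

    Attributes
    ----------
    threshold : float
        Transition-probability cutoff below which a state drop counts as
        a potential lesion boundary.
    margin_px : int
        Width (in pixels) of the exclusion band along the white-matter
        border; boundary pixels at Euclidean distance <= margin_px from
        the nearest out-of-mask pixel are discarded.
    min_boundary_px : int
        Minimum 8-connected boundary component size kept.
    growth_fraction : float
        Region-growing acceptance fraction: a candidate joins when its
        deviation from the region mean is below growth_fraction * sd.
        Exactly 0 disables growth (seeds only).
    max_region_px : int or None
        Safety cap per grown region; None means 10% of the mask area.
    """

    threshold: float = 0.01
    margin_px: int = 2
    min_boundary_px: int = 3
    growth_fraction: float = 0.5
    max_region_px: int | None = None

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.margin_px < 0:
            raise ValueError("margin_px must be >= 0")
        if self.min_boundary_px < 1:
            raise ValueError("min_boundary_px must be >= 1")
        if self.growth_fraction < 0.0:
            raise ValueError("growth_fraction must be >= 0")


@dataclass(frozen=True)
class BoundarySet:
    """Pixels flagged as rare-transition boundaries, plus growth seeds.

    ``seeds`` are the strictly brighter members of at least one rare pair —
    the pixels growth starts from, since injury is hyperintense on T1.
    """

    pixels: frozenset[tuple[int, int]]
    seeds: frozenset[tuple[int, int]]

    def __post_init__(self):
        if not self.seeds <= self.pixels:
            raise ValueError("seeds must be a subset of boundary pixels")

    @classmethod
    def empty(cls) -> "BoundarySet":
        return cls(frozenset(), frozenset())

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class LesionMask:
    """Grown injury regions with 8-connected component labels."""

    mask: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    per_component: tuple[tuple[int, int, tuple[float, float]], ...]
    capped: bool = False

    @property
    def n_components(self) -> int:
        return len(self.per_component)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_mask(cls, mask: np.ndarray, capped: bool = False) -> "LesionMask":
        mask = np.asarray(mask, dtype=bool)
        labels, n = ndimage.label(mask, structure=EIGHT_CONN)
        comps = []
        if n:
            areas = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
            centroids = ndimage.center_of_mass(mask, labels, index=range(1, n + 1))
            comps = [
                (lab, int(a), (float(c[0]), float(c[1])))
                for lab, (a, c) in enumerate(zip(areas, centroids), start=1)
            ]
        return cls(mask=mask, labels=labels, per_component=tuple(comps), capped=capped)


def mark_boundaries(
    states: StateImage, model: TransitionModel, cfg: DetectionConfig
) -> BoundarySet:
    """Flag both pixels of every 8-connected rare-transition pair.

    A pair is rare when ``q * alpha**|ds|`` for its state drop ``ds`` falls
    below ``cfg.threshold``; the strictly brighter pixel becomes a seed.
    Each unordered pair is evaluated exactly once.
    """
    if model.n != states.n:
        raise ValueError(
            f"state-space mismatch: model has n={model.n}, image has n={states.n}"
        )
    s = states.states
    mask = states.mask
    pixels: set[tuple[int, int]] = set()
    seeds: set[tuple[int, int]] = set()
    rows, cols = s.shape
    for dr, dc in NEIGHBOR_OFFSETS:
        a, b, ma, mb = _shifted_views(s, mask, dr, dc)
        valid = ma & mb
        drop = np.abs(a - b)
        rare = valid & (model.probs[np.clip(drop, 0, model.n)] < cfg.threshold)
        rr, cc = np.nonzero(rare)
        # translate window coords back to image coords of both pair members
        r0, c0 = max(dr, 0), max(dc, 0)
        for r, c in zip(rr, cc):
            pa = (int(r + r0 - dr), int(c + c0 - dc))
            pb = (int(r + r0), int(c + c0))
            pixels.add(pa)
            pixels.add(pb)
            if s[pa] > s[pb]:
                seeds.add(pa)
            elif s[pb] > s[pa]:
                seeds.add(pb)
    return BoundarySet(frozenset(pixels), frozenset(seeds))


def remove_margin_false_boundaries(
    b: BoundarySet, mask: np.ndarray, cfg: DetectionConfig
) -> BoundarySet:
    """Drop boundary pixels near the mask border, then tiny components.

    Transitions at the white-matter margin are dominated by partial-volume
    mixing with grey matter (a bright rim), not injury.  Pixels whose
    Euclidean distance to the nearest out-of-mask pixel is <= margin_px
    are removed first; surviving 8-connected components smaller than
    min_boundary_px are then discarded.  Seeds are filtered consistently.
    """
    mask = np.asarray(mask, dtype=bool)
    if not b.pixels:
        return b
    # pad so the image border counts as out-of-mask
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    kept = {p for p in b.pixels if dist[p] > cfg.margin_px}
    if kept and cfg.min_boundary_px > 1:
        img = np.zeros(mask.shape, dtype=bool)
        rows, cols = zip(*kept)
        img[rows, cols] = True
        labels, n = ndimage.label(img, structure=EIGHT_CONN)
        if n:
            sizes = ndimage.sum_labels(img, labels, index=range(1, n + 1))
            small = {lab for lab, sz in enumerate(sizes, 1) if sz < cfg.min_boundary_px}
            kept = {p for p in kept if labels[p] not in small}
    return BoundarySet(frozenset(kept), frozenset(p for p in b.seeds if p in kept))


def grow_regions(
    image: np.ndarray,
    b: BoundarySet,
    mask: np.ndarray,
    cfg: DetectionConfig,
    states: StateImage | np.ndarray | None = None,
) -> LesionMask:
    """Grow lesions from boundary seeds by statistical similarity.

    Seeds are processed in row-major order, skipping those already absorbed
    into an earlier region.  Growth is breadth-first over 8-connected
    in-mask pixels; candidate p joins region R when

        |I(p) - mean(I over R)| / sd(I over R) < growth_fraction.

    While a region is too small for stable statistics (< 4 pixels) or its
    sd is numerically zero, the criterion is undefined and a candidate is
    accepted only if its quantized state equals the seed's state.  Growth
    stops when no candidate qualifies or the region hits max_region_px
    (reported via ``LesionMask.capped``).  Touching regions merge in the
    final 8-connected labeling.

    Parameters
    ----------
    image : 2D float array
        Stretched intensities (the ``stretched`` field of a StateImage).
    states : StateImage or int array, optional
        Quantized states backing the degenerate-sd acceptance rule;
        required whenever seeds exist.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    seeds = sorted(b.seeds)
    if not seeds:
        return LesionMask.from_mask(np.zeros(mask.shape, dtype=bool))
    if states is None:
        raise ValueError("grow_regions needs the quantized states for seeding")
    s = getattr(states, "states", states)
    max_px = cfg.max_region_px
    if max_px is None:
        max_px = max(1, int(0.10 * mask.sum()))

    lesion = np.zeros(mask.shape, dtype=bool)
    rows, cols = mask.shape
    capped = False
    for seed in seeds:
        if lesion[seed]:
            continue
        if cfg.growth_fraction == 0.0:
            lesion[seed] = True
            continue
        seed_state = s[seed]
        region_sum = float(image[seed])
        region_sq = float(image[seed]) ** 2
        count = 1
        lesion[seed] = True
        queue: deque[tuple[int, int]] = deque(_neighbors(seed, rows, cols))
        while queue and count < max_px:
            p = queue.popleft()
            if lesion[p] or not mask[p]:
                continue
            mean = region_sum / count
            var = max(region_sq / count - mean * mean, 0.0)
            sd = var**0.5
            if count < 4 or sd < 1e-6:
                accept = s[p] == seed_state
            else:
                accept = abs(image[p] - mean) / sd < cfg.growth_fraction
            if accept:
                lesion[p] = True
                region_sum += float(image[p])
                region_sq += float(image[p]) ** 2
                count += 1
                queue.extend(_neighbors(p, rows, cols))
        if count >= max_px:
            capped = True
    return LesionMask.from_mask(lesion, capped=capped)


def _neighbors(p: tuple[int, int], rows: int, cols: int):
    r, c = p
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                yield (rr, cc)


def calibrate_threshold(
    states: StateImage, model: TransitionModel, fraction: float = 0.001
) -> float:
    """Empirical threshold: the f-quantile of observed pair probabilities.

    Implements threshold selection from the statistical properties of the
    whole white-matter region: collect the transition probability of every
    8-connected in-mask pair and return the ``fraction`` quantile, so only
    the rarest observed transitions fall below it.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    s = states.states
    mask = states.mask
    probs = []
    for dr, dc in NEIGHBOR_OFFSETS:
        a, b, ma, mb = _shifted_views(s, mask, dr, dc)
        valid = ma & mb
        drop = np.abs(a[valid] - b[valid])
        probs.append(model.probs[np.clip(drop, 0, model.n)])
    all_probs = np.concatenate(probs)
    if all_probs.size == 0:
        raise ValueError("degenerate mask: no adjacent in-mask pairs")
    return float(np.quantile(all_probs, fraction))


def detect(
    image: np.ndarray,
    mask: np.ndarray,
    q: float | str = "estimate",
    n_states: int = 7,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
    cfg: DetectionConfig | None = None,
) -> tuple[LesionMask, dict]:
    """Full pipeline: quantize, fit the transition model, mark, filter, grow.

    Parameters
    ----------
    q : float or "estimate"
        Same-state probability; "estimate" fits it from the slice itself.

    Returns
    -------
    (LesionMask, dict)
        The grown lesion mask and a structured run report (q, alpha,
        threshold, counts per stage).
    """
    cfg = cfg or DetectionConfig()
    try:
        states = stretch_and_quantize(image, mask, n_states, clip_percentiles)
    except ValueError as e:
        raise ValueError(f"quantization failed: {e}") from e
    if q == "estimate":
        q_used = estimate_q(states)
    else:
        q_used = float(q)
    model = TransitionModel.from_q(q_used, states.n)
    raw = mark_boundaries(states, model, cfg)
    filtered = remove_margin_false_boundaries(raw, mask, cfg)
    lesions = grow_regions(states.stretched, filtered, mask, cfg, states)
    report = {
        "q": q_used,
        "q_source": "estimated" if q == "estimate" else "fixed",
        "alpha": model.alpha,
        "n_states": n_states,
        "threshold": cfg.threshold,
        "min_significant_drop": model.min_significant_drop(cfg.threshold),
        "mask_px": int(np.asarray(mask, bool).sum()),
        "boundary_px_raw": len(raw.pixels),
        "boundary_px_kept": len(filtered.pixels),
        "seeds_raw": len(raw.seeds),
        "seeds_kept": len(filtered.seeds),
        "n_components": lesions.n_components,
        "lesion_px": lesions.area_px,
        "capped": lesions.capped,
        "config": {
            "threshold": cfg.threshold,
            "margin_px": cfg.margin_px,
            "min_boundary_px": cfg.min_boundary_px,
            "growth_fraction": cfg.growth_fraction,
            "max_region_px": cfg.max_region_px,
            "n_states": n_states,
            "clip_percentiles": list(clip_percentiles),
        },
    }
    return lesions, report
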