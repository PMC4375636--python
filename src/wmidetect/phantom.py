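"""Synthetic 2D slice phantoms with known white matter and lesion ground truth.

A phantom emulates the features of a neonatal T1 slice that the detector
actually relies on: a compact, irregularly shaped white-matter region; a
smoothly varying background intensity inside it (maturation and coil-shading
gradients); spatially correlated additive noise; and small bright punctate
lesions — isolated or clustered — of known location and area.  An optional
bright rim along the mask border emulates grey-matter contamination from an
imperfect white-matter segmentation.

No MR physics is modelled (no bias field, no Rician noise): the detector
contract only involves local intensity transitions, for which a smoothed
Gaussian noise field is an adequate stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = ["LesionSpec", "PhantomSpec", "generate", "generate_suite"]


@dataclass(frozen=True)
class LesionSpec:
    """One punctate bright lesion.

    ``contrast`` is expressed as a multiple of the background noise sd,
    added on top of the local background; ``shape`` is "disc" for an exact
    rasterized disc or "blob" for a disc warped by a low-frequency radial
    perturbation (irregular punctate lesions).  Blob geometry derives only
    from the lesion's own fields, so ground truth never depends on the
    phantom noise seed.
    """

    center: tuple[int, int]
    radius: float = 3.0
    contrast: float = 6.0
    shape: str = "disc"
    shape_seed: int = 0

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"lesion radius must be >= 1, got {self.radius}")
        if self.contrast <= 0:
            raise ValueError(f"lesion contrast must be > 0, got {self.contrast}")
        if self.shape not in ("disc", "blob"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary footprint of the lesion on an image grid."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        dist = np.hypot(dr, dc)
        if self.shape == "disc":
            return dist <= self.radius
        rng = np.random.default_rng(
            [self.shape_seed, int(self.center[0]), int(self.center[1])]
        )
        amps = rng.uniform(-1.0, 1.0, size=2)
        phases = rng.uniform(0.0, 2 * np.pi, size=2)
        theta = np.arctan2(dr, dc)
        warp = 1.0 + 0.3 * (
            amps[0] * np.cos(2 * theta + phases[0])
            + amps[1] * np.cos(3 * theta + phases[1])
        )
        return dist <= self.radius * np.clip(warp, 0.4, None)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Defaults describe the nominal study conditions: a 128x128 slice, a
    white-matter blob covering roughly a quarter of it, background
    intensity 0.5 (arbitrary units) with a mild +/-0.02 shading gradient
    (normal unmyelinated white matter is fairly homogeneous on early T1),
    and correlated noise of sd 0.01 (correlation length ~2.5 px, matching
    the in-plane smoothness of reconstructed MR data).  Punctate lesions
    default to radius 3 px at 6x the noise sd — conspicuously hyperintense
    relative to the normal-tissue variation, as real punctate WMI is.
    """

    shape: tuple[int, int] = (128, 128)
    wm_axes: tuple[float, float] = (34.0, 40.0)
    wm_perturb: float = 0.10
    base_intensity: float = 0.5
    gradient_amplitude: float = 0.02
    noise_sd: float = 0.01
    noise_smooth_px: float = 2.5
    outside_intensity: float = 0.15
    lesions: tuple[LesionSpec, ...] = ()
    rim_width: int = 0
    rim_contrast: float = 6.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.rim_width < 0:
            raise ValueError("rim_width must be >= 0")


def _wm_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ellipse with a random low-frequency boundary perturbation."""
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = (rr - (rows - 1) / 2.0) / spec.wm_axes[0]
    dc = (cc - (cols - 1) / 2.0) / spec.wm_axes[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(dr, dc)
    amps = rng.uniform(-1.0, 1.0, size=3)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    wobble = sum(
        a * np.cos(k * theta + p) for k, (a, p) in zip((2, 3, 5), zip(amps, phases))
    )
    return rho <= 1.0 + spec.wm_perturb * wobble


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth shading: a random planar tilt plus one broad Gaussian bump."""
    rows, cols = spec.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    half = max(rows, cols) / 2.0
    phi = rng.uniform(0.0, 2 * np.pi)
    plane = (
        np.cos(phi) * (rr - rows / 2.0) + np.sin(phi) * (cc - cols / 2.0)
    ) / half
    bump_center = rng.uniform(0.25, 0.75, size=2) * np.array([rows, cols])
    bump_sigma = rng.uniform(0.3, 0.6) * half
    bump = np.exp(
        -((rr - bump_center[0]) ** 2 + (cc - bump_center[1]) ** 2)
        / (2 * bump_sigma**2)
    )
    bump_sign = rng.choice([-1.0, 1.0])
    g = plane + 0.5 * bump_sign * bump
    return spec.base_intensity + spec.gradient_amplitude * g


def _noise(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.shape)
    if spec.noise_smooth_px > 0:
        smooth = ndimage.gaussian_filter(white, spec.noise_smooth_px)
    else:
        smooth = white
    # renormalize so the realized field has exactly the requested sd
    return smooth * (spec.noise_sd / smooth.std())


def generate(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Render a phantom slice.

    Returns
    -------
    (image, wm_mask, truth_mask, manifest)
        Float image, boolean white-matter mask, boolean lesion ground
        truth, and a manifest recording every lesion's geometry.  Fully
        deterministic for a fixed seed; the ground truth depends only on
        the lesion specs, never on the noise draw.

    Raises
    ------
    ValueError
        If any lesion pixel falls outside the white-matter mask.
    """
    rng = np.random.default_rng(spec.seed)
    wm = _wm_mask(spec, rng)
    image = np.full(spec.shape, spec.outside_intensity, dtype=float)
    inside = _background(spec, rng) + _noise(spec, rng)
    image[wm] = inside[wm]

    if spec.rim_width > 0:
        dist = ndimage.distance_transform_edt(wm)
        rim = wm & (dist <= spec.rim_width)
        image[rim] += spec.rim_contrast * spec.noise_sd

    truth = np.zeros(spec.shape, dtype=bool)
    manifest_lesions = []
    for i, lesion in enumerate(spec.lesions):
        foot = lesion.rasterize(spec.shape)
        if not foot.any():
            raise ValueError(f"lesion {i} rasterizes to zero pixels")
        if (foot & ~wm).any():
            raise ValueError(
                f"lesion {i} at {lesion.center} extends outside the "
                "white-matter mask"
            )
        image[foot] += lesion.contrast * spec.noise_sd
        truth |= foot
        manifest_lesions.append(
            {
                "center": [int(lesion.center[0]), int(lesion.center[1])],
                "radius": float(lesion.radius),
                "contrast": float(lesion.contrast),
                "shape": lesion.shape,
                "area_px": int(foot.sum()),
            }
        )

    manifest = {
        "seed": int(spec.seed),
        "shape": [int(s) for s in spec.shape],
        "wm_area_px": int(wm.sum()),
        "noise_sd": float(spec.noise_sd),
        "lesions": manifest_lesions,
        "rim": (
            {"width_px": int(spec.rim_width), "contrast": float(spec.rim_contrast)}
            if spec.rim_width > 0
            else None
        ),
    }
    return image, wm, truth, manifest


def generate_suite(
    n_images: int,
    lesion_prevalence: float = 0.5,
    seed: int = 0,
    *,
    base_spec: PhantomSpec | None = None,
    min_lesions: int = 2,
    max_lesions: int = 5,
    radius_range: tuple[int, int] = (3, 5),
    contrast_range: tuple[float, float] = (5.0, 8.0),
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, dict]]:
    """Reproducible batch of phantoms for statistical evaluation.

    ``round(lesion_prevalence * n_images)`` phantoms carry lesions (the
    first ones in the returned list); the rest are lesion-free.  Lesioned
    phantoms receive 2-5 lesions (punctate WMI is characteristically
    multi-focal) with radius and contrast drawn from the given ranges,
    placed well inside the white matter; a lesion is placed adjacent to
    the previous one half of the time to emulate clustered punctate
    injury.  Fixed seed gives a byte-identical suite.
    """
    if not 0.0 <= lesion_prevalence <= 1.0:
        raise ValueError("lesion_prevalence must lie in [0, 1]")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_lesioned = round(lesion_prevalence * n_images)
    out = []
    for i in range(n_images):
        child_seed = int(rng.integers(1, 2**31 - 1))
        spec = replace(base, seed=child_seed, lesions=())
        if i < n_lesioned:
            _, wm, _, _ = generate(spec)
            lesions = _place_lesions(
                wm,
                rng,
                rng.integers(min_lesions, max_lesions + 1),
                radius_range,
                contrast_range,
            )
            spec = replace(spec, lesions=tuple(lesions))
        out.append(generate(spec))
    return out


def _place_lesions(wm, rng, n_lesions, radius_range, contrast_range):
    """Sample lesion specs well inside the mask, sometimes clustered."""
    dist = ndimage.distance_transform_edt(wm)
    lesions: list[LesionSpec] = []
    prev_center = None
    for j in range(int(n_lesions)):
        radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
        contrast = float(rng.uniform(*contrast_range))
        # keep the whole lesion clear of the margin exclusion band
        allowed = dist > radius + 5
        center = None
        if prev_center is not None and rng.random() < 0.5:
            for _ in range(50):  # try to cluster next to the previous lesion
                ang = rng.uniform(0, 2 * np.pi)
                gap = rng.uniform(2.2, 3.2) * radius
                cand = (
                    int(round(prev_center[0] + gap * np.sin(ang))),
                    int(round(prev_center[1] + gap * np.cos(ang))),
                )
                if (
                    0 <= cand[0] < wm.shape[0]
                    and 0 <= cand[1] < wm.shape[1]
                    and allowed[cand]
                ):
                    center = cand
                    break
        if center is None:
            choices = np.argwhere(allowed)
            if choices.size == 0:
                raise ValueError("white-matter mask too small to place lesions")
            center = tuple(int(v) for v in choices[rng.integers(len(choices))])
        shape = "disc" if rng.random() < 0.5 else "blob"
        lesions.append(
            LesionSpec(
                center=center,
                radius=radius,
                contrast=contrast,
                shape=shape,
                shape_seed=j,
            )
        )
        prev_center = center
    return lesions
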