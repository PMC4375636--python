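"""Scikit-learn style estimators wrapping the detection pipeline.

Two estimators are exposed:

``StateQuantizer``
    a transformer that learns a percentile stretch from one slice's masked
    intensities and maps slices to integer state images;

``WMIDetector``
    the full detector: ``fit`` estimates the transition-model parameter q
    (or accepts a fixed one) and solves for the decay rate alpha;
    ``predict`` returns the binary lesion mask for a slice.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``clone``-ability), so they compose
with sklearn model-selection utilities.  The white-matter mask travels as
a keyword argument alongside the image, mirroring how sample weights do.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .detection import (
    DetectionConfig,
    LesionMask,
    grow_regions,
    mark_boundaries,
    remove_margin_false_boundaries,
)
from .quantize import stretch_and_quantize
from .transition import TransitionModel, estimate_q

__all__ = ["StateQuantizer", "WMIDetector"]


def _check_slice(X, mask):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {X.shape}")
    if mask is None:
        mask = np.ones(X.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != X.shape:
        raise ValueError("mask geometry mismatch")
    return X, mask


class StateQuantizer(TransformerMixin, BaseEstimator):
    """Percentile histogram stretch + equal-width state binning.

    Parameters
    ----------
    n_states : int, default=7
        Number of intensity states N + 1.
    clip_percentiles : (float, float), default=(1.0, 99.0)
        In-mask percentile range mapped onto [0, 1] before binning.

    Attributes
    ----------
    low_, high_ : float
        Raw intensities mapped to 0 and 1 by the learned stretch.
    state_image_ : StateImage
        Quantization of the slice seen at fit time.
    """

    def __init__(self, n_states: int = 7, clip_percentiles=(1.0, 99.0)):
        self.n_states = n_states
        self.clip_percentiles = clip_percentiles

    def fit(self, X, y=None, *, mask=None):
        X, mask = _check_slice(X, mask)
        si = stretch_and_quantize(X, mask, self.n_states, tuple(self.clip_percentiles))
        self.low_, self.high_ = si.source_stats
        self.state_image_ = si
        return self

    def transform(self, X, *, mask=None) -> np.ndarray:
        """Quantize a slice with the stretch learned at fit time."""
        check_is_fitted(self, "state_image_")
        X, mask = _check_slice(X, mask)
        space = self.state_image_.space
        states = np.full(X.shape, -1, dtype=np.int64)
        if self.high_ > self.low_:
            norm = np.clip((X[mask] - self.low_) / (self.high_ - self.low_), 0.0, 1.0)
            states[mask] = space.assign(norm)
        else:
            states[mask] = 0
        return states


class WMIDetector(BaseEstimator):
    """White-matter injury detector over 2D T1 slices.

    The detector quantizes masked intensities into states, models the
    state drop between 8-connected neighbours with the one-parameter
    geometric law ``P(drop = k) = q * alpha**k``, flags pairs whose drop
    probability falls below ``threshold`` as lesion boundaries, prunes
    boundaries along the white-matter margin, and grows bright lesions
    from the surviving seeds.

    Parameters
    ----------
    n_states : int, default=7
        Number of intensity states.
    q : float or "estimate", default="estimate"
        Same-state probability; "estimate" derives it from the slice as
        the fraction of equal-state neighbour pairs.
    threshold : float, default=0.01
        Rare-transition probability cutoff.
    margin_px : int, default=2
        Mask-border exclusion band width.
    min_boundary_px : int, default=3
        Minimum surviving boundary component size.
    growth_fraction : float, default=0.5
        Region-growing acceptance fraction (deviation / sd).
    max_region_px : int or None, default=None
        Per-region growth cap; None means 10% of the mask area.
    clip_percentiles : (float, float), default=(1.0, 99.0)
        Stretch percentiles.

    Attributes
    ----------
    q_ : float
        Same-state probability actually used.
    alpha_ : float
        Fitted geometric decay rate.
    model_ : TransitionModel
        The fitted transition law.
    report_ : dict
        Structured run report of the last ``fit``.

    Examples
    --------
    >>> from wmidetect.phantom import PhantomSpec, generate
    >>> img, wm, truth, _ = generate(PhantomSpec(seed=7))
    >>> det = WMIDetector().fit(img, mask=wm)
    >>> lesions = det.predict(img, mask=wm)
    >>> bool(lesions[truth].any())
    True
    """

    def __init__(
        self,
        n_states: int = 7,
        q="estimate",
        threshold: float = 0.01,
        margin_px: int = 2,
        min_boundary_px: int = 3,
        growth_fraction: float = 0.5,
        max_region_px: int | None = None,
        clip_percentiles=(1.0, 99.0),
    ):
        self.n_states = n_states
        self.q = q
        self.threshold = threshold
        self.margin_px = margin_px
        self.min_boundary_px = min_boundary_px
        self.growth_fraction = growth_fraction
        self.max_region_px = max_region_px
        self.clip_percentiles = clip_percentiles

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            threshold=self.threshold,
            margin_px=self.margin_px,
            min_boundary_px=self.min_boundary_px,
            growth_fraction=self.growth_fraction,
            max_region_px=self.max_region_px,
        )

    def fit(self, X, y=None, *, mask=None):
        """Fit the transition model on one masked slice.

        Estimates q from equal-state neighbour pairs (unless a fixed q was
        given) and solves the normalization polynomial for alpha.
        """
        X, mask = _check_slice(X, mask)
        si = stretch_and_quantize(
            X, mask, self.n_states, tuple(self.clip_percentiles)
        )
        q = estimate_q(si) if self.q == "estimate" else float(self.q)
        self.model_ = TransitionModel.from_q(q, si.n)
        self.q_ = q
        self.alpha_ = self.model_.alpha
        return self

    def detect(self, X, *, mask=None) -> tuple[LesionMask, dict]:
        """Run the full pipeline on a slice with the fitted model."""
        check_is_fitted(self, "model_")
        X, mask = _check_slice(X, mask)
        cfg = self._config()
        si = stretch_and_quantize(
            X, mask, self.n_states, tuple(self.clip_percentiles)
        )
        raw = mark_boundaries(si, self.model_, cfg)
        kept = remove_margin_false_boundaries(raw, mask, cfg)
        lesions = grow_regions(si.stretched, kept, mask, cfg, si)
        report = {
            "q": self.q_,
            "alpha": self.alpha_,
            "threshold": self.threshold,
            "boundary_px_raw": len(raw.pixels),
            "boundary_px_kept": len(kept.pixels),
            "seeds_kept": len(kept.seeds),
            "n_components": lesions.n_components,
            "lesion_px": lesions.area_px,
            "capped": lesions.capped,
        }
        self.report_ = report
        return lesions, report

    def predict(self, X, *, mask=None) -> np.ndarray:
        """Binary lesion mask for a slice (bool array, True = injury)."""
        lesions, _ = self.detect(X, mask=mask)
        return lesions.mask

    def fit_predict(self, X, y=None, *, mask=None) -> np.ndarray:
        return self.fit(X, mask=mask).predict(X, mask=mask)
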