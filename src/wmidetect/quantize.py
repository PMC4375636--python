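"""Histogram stretching and interval quantization of white-matter intensities.

Raw slice intensities inside the white-matter mask are clipped to a robust
percentile range, rescaled to [0, 1], and binned into N + 1 equal-width
states.  Working in states rather than raw grey values makes the transition
model insensitive to scanner gain and per-slice brightness offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .transition import StateSpace

__all__ = ["StateImage", "stretch_and_quantize"]

SENTINEL = -1


@dataclass(frozen=True)
class StateImage:
    """Per-pixel quantized state labels over a white-matter mask.

    Attributes
    ----------
    states : np.ndarray
        2D int array; values in {0..N} inside the mask, -1 outside.
    space : StateSpace
        The interval scheme used for binning.
    source_stats : tuple of float
        (low, high) raw intensities the stretch mapped to 0 and 1.
    stretched : np.ndarray
        2D float array of clipped, [0, 1]-rescaled intensities (0 outside
        the mask); the region-growing stage consumes these.
    """

    states: np.ndarray = field(repr=False)
    space: StateSpace
    source_stats: tuple[float, float]
    stretched: np.ndarray = field(repr=False)

    @property
    def mask(self) -> np.ndarray:
        return self.states >= 0

    @property
    def n(self) -> int:
        return self.space.n


def stretch_and_quantize(
    image: np.ndarray,
    mask: np.ndarray,
    n_states: int = 7,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
) -> StateImage:
    """Clip, rescale and bin in-mask intensities into ``n_states`` states.

    Percentiles are computed over in-mask pixels only, so out-of-mask
    content (skull, CSF, background air) never influences the stretch.
    Bins are half-open ``[a, b)`` with the final bin closed; a constant
    in-mask image collapses to state 0 with a warning rather than erroring.

    Parameters
    ----------
    image : 2D float array
        Raw grayscale slice.
    mask : 2D bool array
        White-matter delineation; must be non-empty and match ``image``.
    n_states : int
        Number of states N + 1 (>= 2).
    clip_percentiles : (low, high)
        Percentile pair in [0, 100], low < high.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {image.shape}")
    if mask.shape != image.shape:
        raise ValueError(
            f"mask geometry mismatch: image {image.shape} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty white-matter mask")
    low_p, high_p = clip_percentiles
    if not 0.0 <= low_p < high_p <= 100.0:
        raise ValueError(f"invalid clip percentiles {clip_percentiles}")
    space = StateSpace(n_states)

    inside = image[mask]
    low, high = np.percentile(inside, [low_p, high_p])
    stretched = np.zeros_like(image)
    states = np.full(image.shape, SENTINEL, dtype=np.int64)
    if high <= low:
        warnings.warn(
            "zero dynamic range inside mask; all pixels assigned state 0",
            stacklevel=2,
        )
        states[mask] = 0
        return StateImage(states, space, (float(low), float(high)), stretched)

    norm = np.clip((image[mask] - low) / (high - low), 0.0, 1.0)
    stretched[mask] = norm
    states[mask] = space.assign(norm)
    return StateImage(states, space, (float(low), float(high)), stretched)
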