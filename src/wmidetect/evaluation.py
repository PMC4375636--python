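"""Agreement machinery for comparing detections against expert delineations.

Three complementary views are provided: a per-pixel accuracy-distance
histogram (how far each detected pixel lies from the nearest ground-truth
pixel), a Bland-Altman analysis of per-case lesion areas (bias and 1.96-sd
limits of agreement), and a binned table of area differences along the
mean-area axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DistanceHistogram",
    "BlandAltmanSummary",
    "accuracy_distance_histogram",
    "bland_altman",
    "binned_difference_table",
    "area_cm2",
]


@dataclass(frozen=True)
class DistanceHistogram:
    """Histogram of detected-pixel distances to the nearest truth pixel.

    ``counts`` maps integer pixel distance (Euclidean, rounded half-up) to
    the number of detected pixels at that distance; distance 0 means the
    pixel lies inside the ground truth.  When the ground truth is empty
    but detections exist, every detected pixel lands in the distinguished
    ``no_truth_count`` bucket instead.
    """

    counts: dict[int, int]
    no_truth_count: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.no_truth_count


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Per-case area agreement with bias and limits of agreement.

    The difference convention is ``gt - auto`` (ground truth minus
    automatic), so a detector that systematically under-segments — as one
    hugging the bright lesion core does — shows a positive bias.
    """

    per_case: tuple[tuple[float, float], ...]  # (mean_area, diff_area) cm^2
    bias: float
    sd: float
    loa_low: float
    loa_high: float


def accuracy_distance_histogram(detected, truth: np.ndarray) -> DistanceHistogram:
    """Distance histogram of detected pixels relative to ground truth.

    Parameters
    ----------
    detected : LesionMask or 2D bool array
    truth : 2D bool array
        Expert delineation on the same pixel grid.
    """
    det = np.asarray(getattr(detected, "mask", detected), dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if det.shape != truth.shape:
        raise ValueError("mask geometry mismatch between detection and truth")
    n_det = int(det.sum())
    if n_det == 0:
        return DistanceHistogram(counts={})
    if not truth.any():
        return DistanceHistogram(counts={}, no_truth_count=n_det)
    dist = ndimage.distance_transform_edt(~truth)
    d = np.floor(dist[det] + 0.5).astype(int)  # round half-up
    values, counts = np.unique(d, return_counts=True)
    return DistanceHistogram(counts={int(v): int(c) for v, c in zip(values, counts)})


def bland_altman(areas_auto, areas_gt) -> BlandAltmanSummary:
    """Bland-Altman agreement between automatic and ground-truth areas.

    Differences are ``gt - auto``; the limits of agreement are
    ``bias +/- 1.96 * sd`` with the sample standard deviation (ddof=1),
    which needs at least two cases.
    """
    auto = np.asarray(areas_auto, dtype=float)
    gt = np.asarray(areas_gt, dtype=float)
    if auto.shape != gt.shape or auto.ndim != 1:
        raise ValueError(
            f"area lists must be equal-length 1D, got {auto.shape} vs {gt.shape}"
        )
    if auto.size == 0:
        raise ValueError("empty area lists")
    if auto.size < 2:
        raise ValueError("need >= 2 cases for limits of agreement")
    means = (auto + gt) / 2.0
    diffs = gt - auto
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanSummary(
        per_case=tuple(zip(means.tolist(), diffs.tolist())),
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def binned_difference_table(
    summary: BlandAltmanSummary, bin_width: float = 0.1
) -> pd.DataFrame:
    """Average area difference per mean-area bin.

    Cases are bucketed along the mean-area axis into ``[k*w, (k+1)*w)``
    bins; empty bins are omitted.  Columns: bin_low, bin_high, mean_diff,
    n_cases.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    per_case = np.asarray(summary.per_case, dtype=float)
    bins = np.floor(per_case[:, 0] / bin_width).astype(int)
    rows = []
    for k in sorted(set(bins.tolist())):
        sel = bins == k
        rows.append(
            {
                "bin_low": k * bin_width,
                "bin_high": (k + 1) * bin_width,
                "mean_diff": float(per_case[sel, 1].mean()),
                "n_cases": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_diff", "n_cases"])


def area_cm2(mask: np.ndarray, pixel_spacing: tuple[float, float] | None) -> float:
    """Lesion area in cm^2 from a binary mask and pixel spacing in mm."""
    if pixel_spacing is None:
        raise ValueError(
            "pixel spacing unknown: supply (row_mm, col_mm), e.g. from the "
            "NIfTI header or the acquisition protocol"
        )
    row_mm, col_mm = pixel_spacing
    if row_mm <= 0 or col_mm <= 0:
        raise ValueError(f"pixel spacing must be positive, got {pixel_spacing}")
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    return float(mask.sum()) * row_mm * col_mm / 100.0
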