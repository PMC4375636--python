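"""Reading slices and masks, writing detection outputs.

Supported inputs are NIfTI volumes (a named slice is extracted and pixel
spacing read from the header) and 8/16-bit PNG/TIFF slice images (spacing
must be supplied, there being no header to read it from).  Outputs are
0/255 PNG or 0/1 NIfTI masks, a JSON run report embedding the fully
resolved configuration, and CSV evaluation tables.  Coordinates are
0-based (row, col), row-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = ["SlicePair", "read_slice", "read_mask_file", "write_mask", "write_outputs"]

NIFTI_SUFFIXES = (".nii", ".nii.gz")


@dataclass(frozen=True)
class SlicePair:
    """One 2D slice with its white-matter mask and optional ground truth."""

    image: np.ndarray = field(repr=False)
    wm_mask: np.ndarray = field(repr=False)
    truth_mask: np.ndarray | None = field(repr=False, default=None)
    spacing: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.wm_mask.shape != self.image.shape:
            raise ValueError(
                f"mask geometry mismatch: image {self.image.shape} vs "
                f"mask {self.wm_mask.shape}"
            )
        if self.truth_mask is not None and self.truth_mask.shape != self.image.shape:
            raise ValueError("mask geometry mismatch: truth mask")
        if self.spacing is not None and any(s <= 0 for s in self.spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.spacing}")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in NIFTI_SUFFIXES)


def _read_nifti_slice(path: Path, slice_index: int, axis: int):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        sl = data
    elif data.ndim == 3:
        if not 0 <= slice_index < data.shape[axis]:
            raise ValueError(
                f"slice index {slice_index} out of range for axis {axis} "
                f"of {path} with shape {data.shape}"
            )
        sl = np.take(data, slice_index, axis=axis)
    else:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")
    zooms = img.header.get_zooms()[:3]
    in_plane = tuple(float(z) for i, z in enumerate(zooms) if i != axis)[:2]
    spacing = in_plane if len(in_plane) == 2 else None
    return np.asarray(sl, dtype=float), spacing


def _read_raster(path: Path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as e:  # pragma: no cover - backend specific
        raise ValueError(f"unreadable image file {path}: {e}") from e
    arr = np.squeeze(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and np.all(arr[..., 0] == arr[..., 1]):
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path} is not grayscale (shape {arr.shape})")
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a 2D image (shape {arr.shape})")
    return np.asarray(arr, dtype=float)


def read_mask_file(
    path: str | Path, slice_index: int = 0, axis: int = 2
) -> np.ndarray:
    """Read a binary mask from NIfTI or PNG/TIFF (nonzero = True)."""
    path = Path(path)
    if _is_nifti(path):
        arr, _ = _read_nifti_slice(path, slice_index, axis)
    else:
        arr = _read_raster(path)
    return arr > 0


def read_slice(
    path: str | Path,
    mask_path: str | Path,
    slice_index: int = 0,
    axis: int = 2,
    spacing: tuple[float, float] | None = None,
    truth_path: str | Path | None = None,
) -> SlicePair:
    """Load an image/mask pair (plus optional ground truth) as a SlicePair.

    For NIfTI inputs the in-plane spacing comes from the header; for
    PNG/TIFF it must be given explicitly when areas in cm^2 are needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        image, header_spacing = _read_nifti_slice(path, slice_index, axis)
        spacing = spacing or header_spacing
    else:
        image = _read_raster(path)
    wm = read_mask_file(mask_path, slice_index, axis)
    truth = read_mask_file(truth_path, slice_index, axis) if truth_path else None
    return SlicePair(
        image=image,
        wm_mask=wm,
        truth_mask=truth,
        spacing=spacing,
        provenance=f"{path}[{slice_index}]" if _is_nifti(path) else str(path),
    )


def write_mask(
    path: str | Path,
    mask: np.ndarray,
    spacing: tuple[float, float] | None = None,
) -> None:
    """Write a binary mask: 0/255 PNG/TIFF or 0/1 NIfTI (suffix decides)."""
    path = Path(path)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if _is_nifti(path):
        sp = spacing or (1.0, 1.0)
        affine = np.diag([sp[0], sp[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))
    else:
        iio.imwrite(path, (mask.astype(np.uint8) * 255))


def write_outputs(
    lesion,
    report: dict,
    out_dir: str | Path,
    spacing: tuple[float, float] | None = None,
    mask_format: str = "png",
) -> dict[str, Path]:
    """Write the lesion mask, JSON report and per-component CSV to a directory.

    The JSON body contains no timestamps, so re-running on identical
    inputs and configuration reproduces files bit for bit.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".nii.gz" if mask_format == "nifti" else ".png"
    mask_path = out_dir / f"lesion_mask{suffix}"
    write_mask(mask_path, lesion.mask, spacing)

    components = [
        {
            "label": lab,
            "area_px": area,
            "centroid_row": cen[0],
            "centroid_col": cen[1],
        }
        for lab, area, cen in lesion.per_component
    ]
    if spacing is not None:
        for comp in components:
            comp["area_cm2"] = comp["area_px"] * spacing[0] * spacing[1] / 100.0

    body = dict(report)
    body["components"] = components
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")

    csv_path = out_dir / "components.csv"
    import pandas as pd

    pd.DataFrame(
        components,
        columns=["label", "area_px", "centroid_row", "centroid_col"]
        + (["area_cm2"] if spacing is not None else []),
    ).to_csv(csv_path, index=False)
    return {"mask": mask_path, "report": report_path, "components": csv_path}
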