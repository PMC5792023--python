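"""Image correction, cell segmentation and per-cell measurements."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .geometry import CellOutline, outline_from_mask
from .stack import MovieStack

__all__ = [
    "correct_offset_and_flatten", "segment_cells", "cell_volume",
    "mean_cell_intensity", "cell_intensity_trace", "average_projection",
    "load_label_masks", "load_polygon_csv", "write_cell_geometry_csv",
]


def cell_volume(outline: CellOutline) -> float:
    """Spherocylinder volume (fL) from the outline's length and width."""
    from .geometry import spherocylinder_volume
    return spherocylinder_volume(outline.length_um, outline.width_um)


def correct_offset_and_flatten(
    stack: MovieStack,
    offset: float,
    flatfield: Optional[np.ndarray] = None,
) -> MovieStack:
    """Subtract the electronic offset and divide by the normalised flatfield.

    The flatfield is normalised to unit mean so the correction preserves the
    mean photometric scale; output values are not clipped and may be
    negative.
    """
    data = stack.data.astype(np.float64) - float(offset)
    if flatfield is not None:
        flatfield = np.asarray(flatfield, dtype=float)
        if flatfield.shape != stack.frame_shape:
            raise ValueError("flatfield shape must match the frames")
        bad = np.argwhere(flatfield <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"flatfield must be strictly positive; pixel ({i}, {j}) is "
                f"{flatfield[i, j]!r}"
            )
        data = data / (flatfield / flatfield.mean())
    return stack.with_data(data)


def segment_cells(
    brightfield: np.ndarray,
    pixel_size_nm: float,
    min_area_um2: float = 0.8,
    max_width_um: float = 1.8,
    min_solidity: float = 0.85,
) -> list[CellOutline]:
    """Segment dark rod-shaped cells from a bright-field-like image.

    Threshold (Otsu on the inverted image), fill holes, drop components that
    touch the border or fall below ``min_area_um2``.  Components that look
    like merged cells (solidity below ``min_solidity`` or width above
    ``max_width_um``) are excluded.  Deterministic: cells are ordered by
    centroid position.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("bright-field image must be 2-D and >= 32x32")
    if np.ptp(img) < 1e-9:
        return []
    try:
        thr = threshold_otsu(img)
    except ValueError:
        return []
    mask = img < thr
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_opening(mask, iterations=1)
    labels = sk_label(mask, connectivity=1)
    px_um = pixel_size_nm / 1000.0
    min_area_px = min_area_um2 / (px_um * px_um)
    h, w = img.shape
    outlines: list[CellOutline] = []
    props = sorted(regionprops(labels),
                   key=lambda p: (p.centroid[0], p.centroid[1]))
    next_id = 0
    for p in props:
        if p.area < min_area_px:
            continue
        rmin, cmin, rmax, cmax = p.bbox
        if rmin == 0 or cmin == 0 or rmax == h or cmax == w:
            continue
        cmask = labels == p.label
        outline = outline_from_mask(cmask, pixel_size_nm, cell_id=next_id)
        if p.solidity < min_solidity or outline.width_um > max_width_um:
            continue        # merged / misshapen component
        outline.cell_id = next_id
        next_id += 1
        outlines.append(outline)
    return outlines


def load_label_masks(label_image: np.ndarray,
                     pixel_size_nm: float) -> list[CellOutline]:
    """Build outlines from an imported label-mask image (label 0 = none)."""
    label_image = np.asarray(label_image)
    outlines = []
    for k, lab in enumerate(np.unique(label_image)):
        if lab == 0:
            continue
        outlines.append(outline_from_mask(label_image == lab, pixel_size_nm,
                                          cell_id=k - 1 if 0 in label_image
                                          else k))
    for i, o in enumerate(outlines):
        o.cell_id = i
    return outlines


def load_polygon_csv(path: str | Path, shape: tuple,
                     pixel_size_nm: float) -> list[CellOutline]:
    """Outlines from a polygon table (columns cell_id, x_px, y_px).

    Each cell's rows list its closed polygon vertices in pixel coordinates;
    the polygon is rasterised onto a ``shape`` canvas.
    """
    from skimage.draw import polygon as sk_polygon

    df = pd.read_csv(path)
    required = {"cell_id", "x_px", "y_px"}
    if not required <= set(df.columns):
        raise ValueError(f"polygon CSV needs columns {sorted(required)}")
    outlines = []
    for k, (cid, grp) in enumerate(df.groupby("cell_id", sort=True)):
        rr, cc = sk_polygon(grp["y_px"].to_numpy(), grp["x_px"].to_numpy(),
                            shape=shape)
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        outlines.append(outline_from_mask(mask, pixel_size_nm, cell_id=k))
    return outlines


def mean_cell_intensity(stack: MovieStack, outline: CellOutline,
                        frame: int = 0) -> float:
    """Arithmetic mean of pixel values inside the cell mask for one frame."""
    if not outline.mask.any():
        raise ValueError("empty cell mask")
    if outline.mask.shape != stack.frame_shape:
        raise ValueError("mask shape does not match frames")
    return float(stack.data[frame][outline.mask].mean())


def cell_intensity_trace(stack: MovieStack, outline: CellOutline,
                         capture_halo_px: int = 0) -> np.ndarray:
    """Mean intensity within the mask for every frame.

    ``capture_halo_px`` integrates over a mask dilated by that many pixels
    but keeps the original pixel count as the reference area (the sum over
    the halo divided by the outline's own pixel count), so that the product
    of the returned per-pixel amplitude and the outline area equals the
    integrated intensity including PSF tails that spill past the outline.
    """
    if not outline.mask.any():
        raise ValueError("empty cell mask")
    if capture_halo_px <= 0:
        return stack.data[:, outline.mask].mean(axis=1)
    halo = ndimage.binary_dilation(outline.mask, iterations=capture_halo_px)
    return stack.data[:, halo].sum(axis=1) / outline.mask.sum()


def average_projection(stack: MovieStack, n_frames: int) -> MovieStack:
    """Pixelwise mean of the first ``n_frames`` frames.

    The result is a single-frame stack whose exposure metadata records the
    effective exposure ``n_frames * frame exposure``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames > stack.n_frames:
        raise ValueError(
            f"n_frames={n_frames} exceeds available frames ({stack.n_frames})"
        )
    proj = stack.data[:n_frames].mean(axis=0)
    return MovieStack(
        data=proj[None],
        pixel_size_nm=stack.pixel_size_nm,
        timestamps_s=np.array([float(stack.timestamps_s[:n_frames].mean())]),
        exposure_ms=stack.exposure_ms * n_frames,
        channel=stack.channel,
    )


def write_cell_geometry_csv(outlines: list[CellOutline],
                            path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame([{
        "cell_id": o.cell_id, "frame": o.frame, "time_s": o.time_s,
        "area_um2": o.area_um2, "length_um": o.length_um,
        "width_um": o.width_um, "volume_fl": o.volume_fl,
    } for o in outlines])
    df.to_csv(path, index=False)
    return df
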