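"""Field image loading and single-cell segmentation.

The segmentation recipe targets unstained brightfield monolayers with
near-uniform background: Gaussian smoothing, a global Otsu threshold on the
inverted image (cells are darker than background), hole filling, 8-connected
labelling, then exclusion of border-touching objects, oversized objects
(treated as cell clusters and dropped, never split) and undersized debris.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure

from .synth import PIXELS_PER_MICRON

__all__ = ["ImageGrid", "CellRegion", "SegmentationParams", "load_image", "segment_field"]

# Area bounds are configured in um^2 so they survive a change of optics;
# at 6 px/um they correspond to 400 and 6000 px^2.
MIN_AREA_UM2 = 400.0 / PIXELS_PER_MICRON**2
MAX_AREA_UM2 = 6000.0 / PIXELS_PER_MICRON**2


@dataclass
class ImageGrid:
    pixels: np.ndarray  # 2-D uint8
    pixel_scale: float = PIXELS_PER_MICRON  # px per micron

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2-D grid")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")


@dataclass
class CellRegion:
    """One segmented cell: cropped mask plus its offset in the field."""

    cell_id: int
    mask: np.ndarray  # bool, cropped to the bounding box
    offset: tuple[int, int]  # (row, col) of the bounding-box origin
    area_px: int
    touches_border: bool

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (rows.mean() + self.offset[0], cols.mean() + self.offset[1])


@dataclass
class SegmentationParams:
    smoothing_sigma: float = 1.0
    min_area_um2: float = MIN_AREA_UM2
    max_area_um2: float = MAX_AREA_UM2
    invert: bool = False  # set if cells are brighter than background


def load_image(path, pixel_scale: float = PIXELS_PER_MICRON) -> ImageGrid:
    """Read a grayscale TIFF/PNG; RGB inputs are converted by channel average."""
    import imageio.v3 as iio

    path = pathlib.Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"could not decode image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:  # RGB(A) -> luminance average over colour channels
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return ImageGrid(pixels=np.clip(np.rint(arr), 0, 255).astype(np.uint8), pixel_scale=pixel_scale)


def segment_field(
    image: ImageGrid, params: SegmentationParams | None = None
) -> list[CellRegion]:
    """Segment a field into single-cell regions.

    Returns regions with stable ids ordered by bounding-box (top, left).
    Blank or constant images yield an empty list.  An apparent foreground
    fraction above one half raises, advising the polarity flag.
    """
    params = params or SegmentationParams()
    px = image.pixels.astype(float)
    if px.max() == px.min():
        return []
    smoothed = ndi.gaussian_filter(px, sigma=params.smoothing_sigma)
    signal = smoothed if params.invert else -smoothed  # cells as maxima
    thresh = filters.threshold_otsu(signal)
    fg = signal > thresh
    frac = fg.mean()
    if frac > 0.5:
        raise ValueError(
            f"foreground fraction {frac:.2f} > 0.5: image polarity looks inverted; "
            "set SegmentationParams(invert=True) if cells are brighter than background"
        )
    fg = ndi.binary_fill_holes(fg)
    labels, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=int))

    scale2 = image.pixel_scale**2
    min_area_px = params.min_area_um2 * scale2
    max_area_px = params.max_area_um2 * scale2
    h, w = fg.shape
    kept = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if touches:
            continue
        if region.area < min_area_px or region.area > max_area_px:
            continue  # debris or cluster
        kept.append((r0, c0, region))

    kept.sort(key=lambda t: (t[0], t[1]))
    regions = []
    for i, (r0, c0, region) in enumerate(kept, start=1):
        regions.append(
            CellRegion(
                cell_id=i,
                mask=region.image.copy(),
                offset=(r0, c0),
                area_px=int(region.area),
                touches_border=False,
            )
        )
    return regions


def region_table(regions: list[CellRegion]) -> pd.DataFrame:
    rows = [
        {
            "cell_id": r.cell_id,
            "area_px": r.area_px,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=["cell_id", "area_px", "centroid_row", "centroid_col"])


def write_label_map(regions: list[CellRegion], shape: tuple[int, int], path) -> None:
    """Write a 16-bit label TIFF from segmented regions."""
    import tifffile

    lab = np.zeros(shape, dtype=np.uint16)
    for r in regions:
        rr, cc = np.nonzero(r.mask)
        lab[rr + r.offset[0], cc + r.offset[1]] = r.cell_id
    tifffile.imwrite(path, lab)
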