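"""Static-image fluorescence quantification.

Background-subtracted mean intensity within a region of interest on a
maximum projection, the measurement used for reporter-induction
comparisons: the ROI is either a hand-drawn polygon around the cell or a
threshold superlevel set, and background is a drawn background region or,
by default, the median of pixels outside the dilated ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path
from scipy import ndimage

__all__ = ["ROI", "QuantResult", "polygon_mask", "quantify_roi", "batch_quantify"]


def polygon_mask(shape: tuple[int, int], vertices) -> np.ndarray:
    """Rasterize a polygon: a pixel is included iff its center lies inside
    (even-odd rule).  Vertices are 0-based (row, col)."""
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3:
        raise ValueError("polygon needs at least 3 (row, col) vertices")
    H, W = shape
    path = Path(verts[:, ::-1])  # matplotlib expects (x, y) = (col, row)
    cols, rows = np.meshgrid(np.arange(W), np.arange(H))
    pts = np.column_stack([cols.ravel(), rows.ravel()])
    mask = path.contains_points(pts).reshape(H, W)
    if not mask.any():
        raise ValueError("polygon covers no pixel centers")
    return mask


@dataclass
class ROI:
    """Polygon or threshold region specification.

    kind 'polygon': `vertices` is a list of (row, col) points.
    kind 'threshold': pixels strictly above `threshold_value` (or above the
    Otsu threshold when `threshold_method` is 'otsu').
    An optional `background_polygon` overrides the default background rule.
    """

    kind: str
    vertices: list | None = None
    threshold_method: str = "fixed"
    threshold_value: float | None = None
    background_polygon: list | None = None

    def validate(self) -> None:
        if self.kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon ROI needs >= 3 vertices")
        elif self.kind == "threshold":
            if self.threshold_method == "fixed" and self.threshold_value is None:
                raise ValueError("fixed threshold ROI needs a value")
            if self.threshold_method not in ("fixed", "otsu"):
                raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh)

    @classmethod
    def from_json(cls, path) -> "ROI":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class QuantResult:
    mean_intensity: float  # background-subtracted counts
    area: int
    background: float
    roi_kind: str


def _roi_mask(image: np.ndarray, roi: ROI) -> np.ndarray:
    if roi.kind == "polygon":
        return polygon_mask(image.shape, roi.vertices)
    if roi.threshold_method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(image.astype(float))
    else:
        thr = roi.threshold_value
    mask = image > thr
    if not mask.any():
        raise ValueError("threshold ROI selected no pixels")
    return mask


def quantify_roi(projection: np.ndarray, roi: ROI,
                 dilate_px: int = 3) -> QuantResult:
    """Background-subtracted mean pixel intensity inside the ROI.

    Background is the mean over the drawn background polygon when provided,
    otherwise the median of pixels outside the ROI mask dilated by
    `dilate_px` (keeping the halo of the object out of the estimate).
    """
    if projection.ndim != 2:
        raise ValueError("quantify_roi expects a 2-D projection")
    roi.validate()
    img = projection.astype(float)
    mask = _roi_mask(img, roi)
    if roi.background_polygon is not None:
        bg = float(img[polygon_mask(img.shape, roi.background_polygon)].mean())
    else:
        dilated = ndimage.binary_dilation(mask, iterations=dilate_px)
        outside = ~dilated
        if not outside.any():
            raise ValueError("no background pixels outside the dilated ROI")
        bg = float(np.median(img[outside]))
    return QuantResult(
        mean_intensity=float(img[mask].mean() - bg),
        area=int(mask.sum()),
        background=bg,
        roi_kind=roi.kind,
    )


def batch_quantify(images: list[np.ndarray],
                   rois: list[ROI | None],
                   conditions: list[str],
                   cells: list[str] | None = None,
                   image_ids: list[str] | None = None) -> pd.DataFrame:
    """Quantify a set of images into a long-format table for group testing.

    A missing ROI (None) produces a flagged row rather than a silent drop.
    Columns: image_id, condition, cell, mean, area, background, missing_roi.
    """
    if not (len(images) == len(rois) == len(conditions)):
        raise ValueError("images, rois and conditions must align")
    cells = cells or [""] * len(images)
    image_ids = image_ids or [f"img{i}" for i in range(len(images))]
    rows = []
    for img_id, img, roi, cond, cell in zip(image_ids, images, rois, conditions, cells):
        if roi is None:
            rows.append({"image_id": img_id, "condition": cond, "cell": cell,
                         "mean": np.nan, "area": 0, "background": np.nan,
                         "missing_roi": True})
            continue
        q = quantify_roi(img, roi)
        rows.append({"image_id": img_id, "condition": cond, "cell": cell,
                     "mean": q.mean_intensity, "area": q.area,
                     "background": q.background, "missing_roi": False})
    return pd.DataFrame(rows)
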