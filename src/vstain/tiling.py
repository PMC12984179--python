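"""Thumbnailing, tissue-contour extraction and center-anchored patch grids.

Whole-slide images are far too large to register or segment directly, so the
pipeline works on a downsampled thumbnail: grayscale conversion, Gaussian
blur, Otsu thresholding, and largest-contour selection yield a tissue mask
whose bounding box anchors a regular patch grid.  Grid coordinates are then
scaled back to full resolution and identical windows are cut from both
stains of a slide pair.

Pixel conventions used throughout the package: 0-based indices, x grows
rightwards (columns), y grows downwards (rows), patch windows are half-open
``[x, x + S) x [y, y + S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import resize

__all__ = [
    "Thumbnail",
    "TissueMask",
    "PatchGrid",
    "make_thumbnail",
    "to_grayscale",
    "gaussian_blur",
    "otsu_threshold",
    "extract_roi",
    "build_patch_grid",
    "extract_patch_pairs",
]

#: Grayscale weights (ITU-R 601 luma): I = 0.299 R + 0.587 G + 0.114 B.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

THUMBNAIL_MAX_DIM = 1024
DEFAULT_BLUR_SIGMA = 2.0


@dataclass
class Thumbnail:
    image: np.ndarray
    #: thumbnail-to-full-resolution ratio (<= 1).
    scale_factor: float

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


@dataclass
class TissueMask:
    binary: np.ndarray
    threshold: float
    degenerate: bool = False
    contour: np.ndarray | None = None          # ordered (x, y) points
    bbox: tuple[int, int, int, int] | None = None   # (x_min, y_min, w, h)
    center: tuple[float, float] | None = None


@dataclass
class PatchGrid:
    patch_size: int
    overlap: int
    n_per_side: int
    #: top-left corners (x_p, y_p) in full-resolution coordinates.
    coords: list[tuple[int, int]] = field(default_factory=list)


def make_thumbnail(img: np.ndarray, max_dim: int = THUMBNAIL_MAX_DIM) -> Thumbnail:
    """Downsample ``img`` so its longest side is at most ``max_dim`` pixels.

    Anti-aliased (area-averaging) downsampling is used so the intensity
    histogram — and hence the Otsu threshold — is preserved.
    """
    h, w = img.shape[:2]
    scale = min(1.0, max_dim / max(h, w))
    if scale == 1.0:
        return Thumbnail(image=img.copy(), scale_factor=1.0)
    out_shape = (max(1, round(h * scale)), max(1, round(w * scale)))
    thumb = resize(img, out_shape + img.shape[2:], anti_aliasing=True,
                   preserve_range=True).astype(img.dtype)
    return Thumbnail(image=thumb, scale_factor=out_shape[1] / w)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Luma grayscale ``I = 0.299 R + 0.587 G + 0.114 B`` at full precision.

    Accepts RGB or RGBA rasters; an alpha channel is ignored.
    """
    if rgb.ndim != 3 or rgb.shape[2] not in (3, 4):
        raise ValueError(f"expected an RGB(A) raster, got shape {rgb.shape}")
    return rgb[..., :3].astype(np.float64) @ GRAY_WEIGHTS


def gaussian_blur(img: np.ndarray, sigma: float = DEFAULT_BLUR_SIGMA) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel; ``sigma == 0`` is identity."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    img = np.asarray(img, dtype=np.float64)
    if sigma == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma, mode="nearest")


def otsu_threshold(img: np.ndarray) -> TissueMask:
    """Otsu's threshold by exhaustive minimization of the intra-class variance.

    Scans all 256 candidate thresholds ``t`` of an 8-bit image and returns the
    minimizer of ``w1(t) s1^2(t) + w2(t) s2^2(t)`` where class 1 holds pixels
    ``<= t`` and class 2 pixels ``> t``.  The binary mask is 1 where the
    (blurred) intensity exceeds ``t``.  A constant image is flagged degenerate
    and yields an all-zero mask rather than raising.
    """
    vals = np.clip(np.round(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if (hist > 0).sum() <= 1:
        return TissueMask(binary=np.zeros(vals.shape, dtype=bool),
                          threshold=float(vals.ravel()[0]), degenerate=True)

    levels = np.arange(256, dtype=np.float64)
    csum = np.cumsum(hist)                 # pixels with value <= t
    cmean = np.cumsum(hist * levels)
    w1 = csum / n
    w2 = 1.0 - w1
    # class means / variances for every threshold t at once
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(csum > 0, cmean / csum, 0.0)
        mu2 = np.where(csum < n, (cmean[-1] - cmean) / (n - csum), 0.0)
        csq = np.cumsum(hist * levels**2)
        var1 = np.where(csum > 0, csq / csum - mu1**2, 0.0)
        var2 = np.where(csum < n, (csq[-1] - csq) / (n - csum) - mu2**2, 0.0)
    within = w1 * var1 + w2 * var2
    within[~np.isfinite(within)] = np.inf
    t = int(np.argmin(within[:-1]))        # t = 255 leaves class 2 empty
    return TissueMask(binary=vals > t, threshold=float(t))


def extract_roi(mask: TissueMask) -> TissueMask:
    """Select the largest connected foreground component as the tissue ROI.

    Fills ``contour`` (boundary of the maximal-area component, ordered (x, y)
    points), ``bbox`` (x_min, y_min, w, h) and ``center``
    ``(x_min + w/2, y_min + h/2)``.  Raises if the mask is empty.
    """
    if mask.degenerate or not mask.binary.any():
        raise ValueError("no tissue found: empty foreground mask")
    labels, n = ndimage.label(mask.binary)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    component = labels == best
    rows = np.any(component, axis=1).nonzero()[0]
    cols = np.any(component, axis=0).nonzero()[0]
    y_min, y_max = int(rows[0]), int(rows[-1])
    x_min, x_max = int(cols[0]), int(cols[-1])
    w, h = x_max - x_min + 1, y_max - y_min + 1
    contours = measure.find_contours(component.astype(float), 0.5)
    contour_rc = max(contours, key=lambda c: len(c)) if contours else np.empty((0, 2))
    contour_xy = contour_rc[:, ::-1]       # (row, col) -> (x, y)
    return TissueMask(binary=component, threshold=mask.threshold,
                      contour=contour_xy, bbox=(x_min, y_min, w, h),
                      center=(x_min + w / 2.0, y_min + h / 2.0))


def build_patch_grid(mask: TissueMask, patch_size: int, overlap: int = 32,
                     scale_factor: float = 1.0) -> PatchGrid:
    """Center-anchored patch grid over the ROI bounding box.

    With patch size S, overlap O and bbox width w (all at full resolution),
    the per-side patch count is ``N = floor((w - O) / (S - O))``; patch
    centers sit at ``x_p = x_c + i (S - O)``, ``y_p = y_c + j (S - O)`` for
    the N integers i, j centered on zero, and the stored coordinates are
    the corresponding top-left corners (center minus S/2) of the half-open
    windows ``[x, x + S)`` — so N = 1 yields a single patch centered on the
    tissue.  ``mask`` lives in thumbnail space; coordinates are mapped to
    full resolution by dividing by ``scale_factor`` and rounding before the
    grid is laid out.
    """
    if overlap < 0 or patch_size <= overlap:
        raise ValueError("require patch_size > overlap >= 0")
    if mask.bbox is None or mask.center is None:
        raise ValueError("mask has no ROI; call extract_roi first")
    inv = 1.0 / scale_factor
    w_full = round(mask.bbox[2] * inv)
    xc = round(mask.center[0] * inv)
    yc = round(mask.center[1] * inv)
    step = patch_size - overlap
    n = (w_full - overlap) // step
    idx = range(-(n // 2), n - n // 2)
    half = patch_size // 2
    coords = [(xc + i * step - half, yc + j * step - half)
              for j in idx for i in idx]
    return PatchGrid(patch_size=patch_size, overlap=overlap, n_per_side=int(n),
                     coords=coords)


def extract_patch_pairs(pair, grid: PatchGrid):
    """Cut identical full-resolution windows from both stains of ``pair``.

    Windows that leave either raster are dropped.  Returns
    ``(patch_pairs, n_dropped)`` where each element of ``patch_pairs`` is a
    :class:`vstain.qc.PatchPair` with QC fields unset.
    """
    from .qc import PatchPair   # local import: qc depends on tiling helpers

    s = grid.patch_size
    out, dropped = [], 0
    for (x, y) in grid.coords:
        he, mt = pair.he_image, pair.mt_image
        if (x < 0 or y < 0 or x + s > min(he.shape[1], mt.shape[1])
                or y + s > min(he.shape[0], mt.shape[0])):
            dropped += 1
            continue
        out.append(PatchPair(he_patch=he[y:y + s, x:x + s].copy(),
                             mt_patch=mt[y:y + s, x:x + s].copy(),
                             coords=(x, y)))
    return out, dropped
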