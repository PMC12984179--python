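"""Keypoint detection and descriptor matching.

SIFT (float descriptors, Euclidean distance) handles slide-scale matching;
ORB (binary descriptors, Hamming distance) handles patch-scale matching.
Both feed an exhaustive nearest-2 matcher with Lowe's ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from skimage.feature import SIFT, ORB

__all__ = ["KeypointSet", "MatchSet", "detect_sift", "detect_orb",
           "match_descriptors", "accept_slide_pair", "RATIO_THRESHOLD",
           "SLIDE_ACCEPT_THRESHOLD"]

#: Lowe's ratio-test threshold, shared by SIFT and ORB matching.
RATIO_THRESHOLD = 0.75

#: minimum fraction of keypoints surviving the ratio test for a slide pair
#: to be considered the same tissue (empirically chosen default).
SLIDE_ACCEPT_THRESHOLD = 0.10


@dataclass
class KeypointSet:
    #: rows of (x, y, scale, orientation)
    keypoints: np.ndarray
    #: float descriptors (N, 128) for SIFT-style; boolean (N, n_bits) for ORB-style
    descriptors: np.ndarray

    def __post_init__(self) -> None:
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("keypoints and descriptors must align")

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]


@dataclass
class MatchSet:
    #: rows of (index_a, index_b, distance)
    pairs: np.ndarray
    metric: str
    ratio_threshold: float

    def __len__(self) -> int:
        return len(self.pairs)


def _as_float_gray(img: np.ndarray) -> np.ndarray:
    g = np.asarray(img, dtype=np.float64)
    if g.max() > 1.0:
        g = g / 255.0
    return g


def detect_sift(img: np.ndarray) -> KeypointSet:
    """SIFT keypoints + 128-d float descriptors on an intensity raster.

    An image too flat or too small for the scale pyramid yields an empty
    set; the caller decides how to proceed.  The scale pyramid starts at
    native resolution (no initial 2x upsampling): thumbnails are already
    band-limited by the area-averaging downsample, and slide-scale
    alignment does not need sub-pixel keypoints.
    """
    det = SIFT(upsampling=1)
    try:
        det.detect_and_extract(_as_float_gray(img))
    except RuntimeError:          # no keypoints found
        return KeypointSet(np.empty((0, 4)), np.empty((0, 128)))
    kp = np.column_stack([det.keypoints[:, 1], det.keypoints[:, 0],
                          det.scales, det.orientations])
    return KeypointSet(kp, det.descriptors.astype(np.float64))


def detect_orb(img: np.ndarray, n_keypoints: int = 500,
               fast_threshold: float = 0.08) -> KeypointSet:
    """ORB keypoints + 256-bit binary descriptors."""
    det = ORB(n_keypoints=n_keypoints, fast_threshold=fast_threshold)
    try:
        det.detect_and_extract(_as_float_gray(img))
    except (RuntimeError, ValueError):
        return KeypointSet(np.empty((0, 4)), np.empty((0, 256), dtype=bool))
    kp = np.column_stack([det.keypoints[:, 1], det.keypoints[:, 0],
                          det.scales, det.orientations])
    return KeypointSet(kp, det.descriptors)


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Bit count of XOR between two binary descriptors."""
    return int(np.sum(np.asarray(a, bool) ^ np.asarray(b, bool)))


def match_descriptors(a: KeypointSet, b: KeypointSet, metric: str = "euclidean",
                      ratio_threshold: float = RATIO_THRESHOLD) -> MatchSet:
    """Exhaustive nearest-2 matching with Lowe's ratio test.

    A descriptor in ``a`` is matched to its nearest neighbour in ``b`` only
    if ``d_best / d_second < ratio_threshold``; ties (ratio 1) are rejected
    for any threshold below 1.  ``metric`` is ``"euclidean"`` for float
    descriptors or ``"hamming"`` for binary ones (bit-count distances).
    """
    if metric not in ("euclidean", "hamming"):
        raise ValueError(f"unknown metric {metric!r}")
    da, db = a.descriptors, b.descriptors
    if metric == "hamming":
        if da.dtype != bool or db.dtype != bool:
            raise ValueError("hamming metric requires binary descriptors")
        dist = cdist(da.astype(np.float64), db.astype(np.float64),
                     "hamming") * da.shape[1]
    else:
        if da.dtype == bool or db.dtype == bool:
            raise ValueError("euclidean metric requires float descriptors")
        dist = cdist(da, db, "euclidean")
    if len(da) == 0 or len(db) < 2:
        return MatchSet(np.empty((0, 3)), metric, ratio_threshold)
    order = np.argsort(dist, axis=1)
    best, second = order[:, 0], order[:, 1]
    d1 = dist[np.arange(len(da)), best]
    d2 = dist[np.arange(len(da)), second]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d2 > 0, d1 / d2, 1.0)
    keep = ratio < ratio_threshold
    pairs = np.column_stack([np.nonzero(keep)[0], best[keep], d1[keep]])
    return MatchSet(pairs, metric, ratio_threshold)


def accept_slide_pair(matches: MatchSet, kp_counts: tuple[int, int],
                      threshold: float = SLIDE_ACCEPT_THRESHOLD):
    """Slide-pair gate: enough keypoints must survive the ratio test.

    Returns ``(accepted, match_fraction)`` where the fraction is surviving
    matches over the smaller keypoint count.  A pair with no keypoints on
    either side is rejected outright.
    """
    lo = min(kp_counts)
    if lo == 0:
        return False, 0.0
    frac = len(matches) / lo
    return frac >= threshold, float(frac)
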