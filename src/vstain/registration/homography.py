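"""RANSAC homography estimation and perspective warping.

A homography maps H&E patch coordinates onto the MT patch plane,
``[x', y', 1]^T ~ H [x, y, 1]^T``, estimated from ratio-test matches by
random-sample consensus and refit by least squares on the inlier set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .features import KeypointSet, MatchSet

__all__ = ["HomographyTransform", "estimate_homography", "apply_homography",
           "warp_homography", "RANSAC_ITERS", "RANSAC_INLIER_PX"]

RANSAC_ITERS = 2000
RANSAC_INLIER_PX = 3.0


@dataclass
class HomographyTransform:
    H: np.ndarray                       # 3x3, h33 normalized to 1
    inlier_mask: np.ndarray | None = None
    reprojection_error: float = np.nan  # sum of squared residuals over inliers

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.shape != (3, 3):
            raise ValueError("H must be 3x3")
        if self.H[2, 2] == 0:
            raise ValueError("degenerate homography: h33 == 0")
        self.H = self.H / self.H[2, 2]
        if np.isclose(np.linalg.det(self.H[:2, :2]), 0.0):
            raise ValueError("degenerate homography: singular upper 2x2 block")

    @classmethod
    def identity(cls) -> "HomographyTransform":
        return cls(np.eye(3))

    def inverse(self) -> "HomographyTransform":
        return HomographyTransform(np.linalg.inv(self.H))


def apply_homography(H: HomographyTransform | np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map (N, 2) points through the projective transform."""
    m = H.H if isinstance(H, HomographyTransform) else np.asarray(H)
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ m.T
    return hom[:, :2] / hom[:, 2:3]


def estimate_homography(matches: MatchSet, kps_a: KeypointSet, kps_b: KeypointSet,
                        seed: int = 0, n_iters: int = RANSAC_ITERS,
                        inlier_px: float = RANSAC_INLIER_PX) -> HomographyTransform:
    """RANSAC homography from matched keypoints, refit on the consensus set.

    Minimal 4-point hypotheses are sampled with a seeded generator; the
    largest consensus (reprojection residual below ``inlier_px``) is refit
    by normalized DLT least squares over all its inliers, which recovers an
    exact homography to machine precision when the matches are noiseless.
    """
    if len(matches) < 4:
        raise ValueError("insufficient correspondences: need >= 4 matches")
    ia = matches.pairs[:, 0].astype(int)
    ib = matches.pairs[:, 1].astype(int)
    src = kps_a.xy[ia]
    dst = kps_b.xy[ib]
    n = len(src)
    rng = np.random.default_rng(seed)
    best_inliers = None
    best_count = -1
    for _ in range(n_iters):
        sel = rng.choice(n, size=4, replace=False)
        tf = ProjectiveTransform.from_estimate(src[sel], dst[sel])
        if not tf:
            continue
        res = np.linalg.norm(tf(src) - dst, axis=1)
        inliers = res < inlier_px
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
    if best_inliers is None or best_count < 4:
        raise ValueError("RANSAC failed: no non-degenerate consensus found")
    tf = ProjectiveTransform.from_estimate(src[best_inliers], dst[best_inliers])
    if not tf:
        raise ValueError("degenerate inlier configuration (collinear points)")
    res = np.linalg.norm(tf(src) - dst, axis=1)
    inliers = res < inlier_px
    err = float(np.sum(res[inliers] ** 2))
    return HomographyTransform(tf.params, inlier_mask=inliers,
                               reprojection_error=err)


def warp_homography(img: np.ndarray, H: HomographyTransform,
                    output_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Warp ``img`` so that source point p lands at H(p).

    Each output pixel (x', y') is sampled from the source at
    ``H^{-1} (x', y')`` with bilinear interpolation; out-of-bounds samples
    are zero-filled.  Integer-translation homographies therefore produce
    pixel-exact shifted copies.
    """
    if np.isclose(np.linalg.det(H.H), 0.0):
        raise ValueError("singular homography cannot be warped")
    inv = ProjectiveTransform(matrix=np.linalg.inv(H.H))
    out = warp(np.asarray(img, dtype=np.float64), inv,
               output_shape=output_shape or img.shape[:2],
               order=1, mode="constant", cval=0.0, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        return np.round(out).astype(img.dtype)
    return out.astype(img.dtype)
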