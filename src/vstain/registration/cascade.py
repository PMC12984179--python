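"""The full SIFT -> homography -> FFD alignment cascade.

Given a slide pair (H&E moving, MT fixed), the cascade:

1. matches SIFT keypoints between the grayscale renderings and gates the
   pair on the ratio-test survival fraction;
2. estimates a RANSAC homography H (H&E -> MT coordinates) and warps the
   H&E slide into the MT frame;
3. refines the residual local misalignment with a B-spline FFD.

For fixture pairs with ground-truth landmarks the per-stage mean landmark
error is tracked in the moving (H&E) frame: a fixed-frame landmark y maps
to the moving frame through ``H^{-1}`` and then the FFD, and the error is
its distance to the true H&E landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..tiling import to_grayscale
from .features import (detect_sift, match_descriptors, accept_slide_pair,
                       RATIO_THRESHOLD, SLIDE_ACCEPT_THRESHOLD)
from .homography import (HomographyTransform, estimate_homography,
                         apply_homography, warp_homography)
from .ffd import register_ffd, warp_ffd, RegistrationResult

__all__ = ["CascadeResult", "register_pair"]


@dataclass
class CascadeResult:
    accepted: bool
    match_fraction: float
    homography: HomographyTransform | None = None
    ffd: RegistrationResult | None = None
    aligned_he: np.ndarray | None = None
    #: mean landmark error (px) after [identity, homography, homography+FFD]
    stage_errors: list[float] = field(default_factory=list)

    def map_fixed_to_moving(self, pts: np.ndarray) -> np.ndarray:
        """Map MT-frame points into the original H&E frame."""
        pts = np.atleast_2d(pts)
        if self.ffd is not None:
            pts = self.ffd.transform.transform_points(pts)
        if self.homography is not None:
            pts = apply_homography(self.homography.inverse(), pts)
        return pts


def _landmark_error(he_pts: np.ndarray, mapped: np.ndarray) -> float:
    return float(np.mean(np.linalg.norm(mapped - he_pts, axis=1)))


def register_pair(pair, seed: int = 0, ratio_threshold: float = RATIO_THRESHOLD,
                  accept_threshold: float = SLIDE_ACCEPT_THRESHOLD,
                  grid_dims: tuple[int, int] = (8, 8), eta: float = 2.0,
                  max_iter: int = 60, sampling_fraction: float = 0.3,
                  run_ffd: bool = True) -> CascadeResult:
    """Run the three-stage cascade on a slide pair.

    ``pair`` needs ``he_image`` and ``mt_image``; if it also carries a
    fixture ``landmark_set`` the per-stage landmark errors are recorded.
    """
    he_gray = to_grayscale(pair.he_image)
    mt_gray = to_grayscale(pair.mt_image)
    kp_he = detect_sift(he_gray)
    kp_mt = detect_sift(mt_gray)
    matches = match_descriptors(kp_he, kp_mt, "euclidean", ratio_threshold)
    accepted, frac = accept_slide_pair(matches, (len(kp_he), len(kp_mt)),
                                       accept_threshold)
    result = CascadeResult(accepted=accepted, match_fraction=frac)

    landmarks = getattr(pair, "landmark_set", None)
    if landmarks is not None:
        he_pts, mt_pts = landmarks.he_points, landmarks.mt_points
        result.stage_errors.append(_landmark_error(he_pts, mt_pts))
    if not accepted:
        return result

    H = estimate_homography(matches, kp_he, kp_mt, seed=seed)
    result.homography = H
    aligned = warp_homography(pair.he_image, H, output_shape=pair.mt_image.shape[:2])
    result.aligned_he = aligned
    if landmarks is not None:
        mapped = apply_homography(H.inverse(), mt_pts)
        result.stage_errors.append(_landmark_error(he_pts, mapped))

    if run_ffd:
        result.ffd = register_ffd(to_grayscale(aligned), mt_gray,
                                  grid_dims=grid_dims, eta=eta, max_iter=max_iter,
                                  sampling_fraction=sampling_fraction, seed=seed)
        result.aligned_he = warp_ffd(aligned, result.ffd.transform)
        if landmarks is not None:
            mapped = result.map_fixed_to_moving(mt_pts)
            result.stage_errors.append(_landmark_error(he_pts, mapped))
    return result
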