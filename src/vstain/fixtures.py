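"""Synthetic paired-slide fixtures with known ground truth.

Clinical H&E/MT slide pairs are consecutive sections: same tissue geometry,
different stains, offset by a global rigid transform plus a smooth local
warp, with per-slide staining variation and scanning artifacts.  This
module renders pseudo-H&E and pseudo-MT images of one shared synthetic
tissue so every downstream stage (tiling, registration, QC, normalization,
translation, evaluation) can be exercised against exact ground truth.

Tissue is a union of random ellipses carrying multi-octave value noise
("Perlin-style" texture) — enough corner structure for SIFT and ORB.  A
fraction of the tissue is designated collagen; the H&E rendering colors
cytoplasm pink and nuclei blue-purple, while the MT rendering recolors the
identical geometry with blue collagen and red cells.  The MT image is
resampled through a known rigid + B-spline-like displacement map, whose
parameters are retained as the registration ground truth, and landmarks
(blob centroids plus extra tissue points) are carried through the exact
transform.

Not modeled: photorealistic histology, scanner optics, out-of-plane
section differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

__all__ = ["SyntheticSlideSpec", "RigidPlusWarp", "LandmarkSet", "SlidePair",
           "generate_slide_pair", "generate_patch_set", "tissue_mask",
           "write_slide_pair"]

BACKGROUND = 250.0
N_LANDMARKS_MIN = 16


@dataclass
class SyntheticSlideSpec:
    width: int = 384
    height: int = 384
    n_blobs: int = 10
    collagen_fraction: float = 0.35
    global_shift: tuple[float, float] = (18.0, -10.0)
    global_rotation: float = 3.0            # degrees
    warp_amplitude: float = 6.0             # px, peak local displacement
    warp_grid: tuple[int, int] = (4, 4)     # control points per axis
    stain_jitter: tuple[float, float] = (0.9, 1.1)
    artifact_fraction: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        for name in ("collagen_fraction", "artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.warp_amplitude > 0.1 * min(self.width, self.height):
            raise ValueError("warp_amplitude above 10% of the slide size makes "
                             "the registration ground truth ill-posed")
        if min(self.warp_grid) < 2:
            raise ValueError("warp_grid needs at least 2 control points per axis")


class RigidPlusWarp:
    """Ground-truth MT->H&E backward map: rigid motion plus a smooth warp.

    ``G(y) = R(-rot) (y - shift - c) + c + d(y)`` where c is the image
    center and d is a smooth displacement field interpolated from a coarse
    control grid.  This is exactly the map a registration cascade must
    recover: resampling the H&E image at G reproduces the MT geometry.
    """

    def __init__(self, shift, rotation_deg, center, ctrl_disp, amplitude, domain):
        self.shift = np.asarray(shift, dtype=np.float64)
        self.rotation_deg = float(rotation_deg)
        self.center = np.asarray(center, dtype=np.float64)
        self.ctrl_disp = np.asarray(ctrl_disp, dtype=np.float64)  # (gy, gx, 2)
        self.amplitude = float(amplitude)
        self.domain = tuple(domain)                               # (h, w)
        h, w = self.domain
        if self.amplitude > 0 and np.abs(self.ctrl_disp).max() > 0:
            fld = resize(self.ctrl_disp, (h, w, 2), order=3, mode="edge",
                         anti_aliasing=False)
            fld *= self.amplitude / np.abs(np.linalg.norm(fld, axis=-1)).max()
        else:
            fld = np.zeros((h, w, 2))
        self.field = fld
        th = np.deg2rad(-self.rotation_deg)
        self._rot = np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])

    @property
    def is_identity(self) -> bool:
        return (not self.shift.any() and self.rotation_deg == 0
                and not self.field.any())

    def _local(self, pts: np.ndarray) -> np.ndarray:
        """Displacement field sampled at (x, y) points (bilinear, edge-held)."""
        xs = np.clip(pts[:, 0], 0, self.domain[1] - 1)
        ys = np.clip(pts[:, 1], 0, self.domain[0] - 1)
        dx = ndimage.map_coordinates(self.field[..., 0], [ys, xs], order=1, mode="nearest")
        dy = ndimage.map_coordinates(self.field[..., 1], [ys, xs], order=1, mode="nearest")
        return np.column_stack([dx, dy])

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        rigid = (pts - self.shift - self.center) @ self._rot.T + self.center
        return rigid + self._local(pts)

    def inverse_points(self, pts: np.ndarray, n_iter: int = 50) -> np.ndarray:
        """Numerical inverse by fixed-point iteration (sub-0.01 px for the
        moderate deformations this generator permits)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        y = pts.copy()
        for _ in range(n_iter):
            y = y - (self(y) - pts)
        return y

    def grid_map(self):
        """Dense (Gy, Gx) sample coordinates for resampling a full slide."""
        h, w = self.domain
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        g = self(pts)
        return g[:, 1].reshape(h, w), g[:, 0].reshape(h, w)

    def to_dict(self) -> dict:
        return {"shift": self.shift.tolist(), "rotation_deg": self.rotation_deg,
                "center": self.center.tolist(), "amplitude": self.amplitude,
                "domain": list(self.domain), "ctrl_disp": self.ctrl_disp.tolist()}


@dataclass
class LandmarkSet:
    he_points: np.ndarray    # (L, 2) (x, y) in the H&E image
    mt_points: np.ndarray    # (L, 2) corresponding points in the MT image

    def __len__(self) -> int:
        return len(self.he_points)


@dataclass
class SlidePair:
    he_image: np.ndarray
    mt_image: np.ndarray
    true_transform: RigidPlusWarp | None = None
    landmark_set: LandmarkSet | None = None
    #: per-slide boolean masks of injected artifact pixels (fixtures only)
    artifact_masks: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _value_noise(rng: np.random.Generator, shape, scales=(6, 12, 24),
                 weights=(1.0, 0.5, 0.25)) -> np.ndarray:
    """Multi-octave smooth noise in [0, 1]."""
    acc = np.zeros(shape)
    for s, wgt in zip(scales, weights):
        coarse = rng.random((s, s))
        acc += wgt * resize(coarse, shape, order=3, mode="edge", anti_aliasing=False)
    acc -= acc.min()
    rng_span = acc.max() or 1.0
    return acc / rng_span


def _render(tissue, collagen, nuclei, texture, palette) -> np.ndarray:
    """Paint an RGB rendering of the shared geometry with a stain palette."""
    h, w = tissue.shape
    img = np.full((h, w, 3), BACKGROUND)
    mod = (0.8 + 0.4 * texture)[..., None]
    cellular = tissue & ~collagen & ~nuclei
    img[cellular] = (palette["cellular"] * mod)[cellular]
    img[collagen & tissue & ~nuclei] = (palette["collagen"] * mod)[collagen & tissue & ~nuclei]
    img[nuclei & tissue] = (palette["nuclei"] * mod)[nuclei & tissue]
    return img


# Brightness ordering (collagen > cytoplasm > nuclei) is kept consistent
# across the two stains, as in real sections where collagen stains palest;
# this is what lets grayscale feature matching and perceptual hashing work
# across stains.
HE_PALETTE = {"cellular": np.array([225.0, 135.0, 175.0]),
              "collagen": np.array([235.0, 150.0, 185.0]),
              "nuclei": np.array([95.0, 60.0, 150.0])}
MT_PALETTE = {"cellular": np.array([185.0, 70.0, 80.0]),
              "collagen": np.array([100.0, 125.0, 210.0]),
              "nuclei": np.array([70.0, 45.0, 100.0])}


def generate_slide_pair(spec: SyntheticSlideSpec) -> SlidePair:
    """Render a matched pseudo-H&E / pseudo-MT slide pair.

    The MT side is the H&E geometry recolored (collagen -> blue, cells ->
    red), displaced by the returned ground-truth transform, with per-slide
    stain jitter and blank/fold artifacts applied.  Fixed seed implies
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # -- shared tissue geometry ------------------------------------------
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    tissue = np.zeros((h, w), dtype=bool)
    centroids = []
    for _ in range(spec.n_blobs):
        cx = rng.uniform(0.25 * w, 0.75 * w)
        cy = rng.uniform(0.25 * h, 0.75 * h)
        ax = rng.uniform(0.12, 0.26) * w
        ay = rng.uniform(0.12, 0.26) * h
        th = rng.uniform(0, np.pi)
        xr = (xs - cx) * np.cos(th) + (ys - cy) * np.sin(th)
        yr = -(xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
        blob = (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0
        tissue |= blob
        centroids.append((cx, cy))

    texture = _value_noise(rng, (h, w))
    collagen_field = _value_noise(rng, (h, w), scales=(4, 8, 16))
    nuclei_field = _value_noise(rng, (h, w), scales=(16, 32, 64))
    tvals = collagen_field[tissue]
    if spec.collagen_fraction in (0.0, 1.0) or tvals.size == 0:
        collagen = np.full((h, w), spec.collagen_fraction == 1.0)
    else:
        cut = np.quantile(tvals, 1.0 - spec.collagen_fraction)
        collagen = collagen_field > cut
    nuclei = nuclei_field > np.quantile(nuclei_field[tissue], 0.88) if tissue.any() \
        else np.zeros((h, w), dtype=bool)

    he = _render(tissue, collagen, nuclei, texture, HE_PALETTE)
    mt_ideal = _render(tissue, collagen, nuclei, texture, MT_PALETTE)

    # -- ground-truth displacement ---------------------------------------
    ctrl = rng.normal(size=(spec.warp_grid[1], spec.warp_grid[0], 2))
    transform = RigidPlusWarp(shift=spec.global_shift,
                              rotation_deg=spec.global_rotation,
                              center=(w / 2.0, h / 2.0), ctrl_disp=ctrl,
                              amplitude=spec.warp_amplitude, domain=(h, w))
    if transform.is_identity:
        mt = mt_ideal.copy()
    else:
        gy, gx = transform.grid_map()
        mt = np.stack([ndimage.map_coordinates(mt_ideal[..., c], [gy, gx],
                                               order=1, mode="constant",
                                               cval=BACKGROUND)
                       for c in range(3)], axis=-1)

    # -- landmarks: blob centroids + extra texture points ----------------
    he_pts = list(centroids)
    inside = np.argwhere(ndimage.binary_erosion(tissue, iterations=8))
    while len(he_pts) < N_LANDMARKS_MIN and len(inside):
        r, c = inside[rng.integers(len(inside))]
        he_pts.append((float(c), float(r)))
    he_pts = np.asarray(he_pts, dtype=np.float64)
    mt_pts = he_pts.copy() if transform.is_identity else transform.inverse_points(he_pts)
    landmarks = LandmarkSet(he_points=he_pts, mt_points=mt_pts)

    # -- per-slide stain jitter and artifacts ----------------------------
    lo, hi = spec.stain_jitter
    he = he * rng.uniform(lo, hi, size=3)
    mt = mt * rng.uniform(lo, hi, size=3)
    masks = {"he": _inject_artifacts(he, spec.artifact_fraction, rng),
             "mt": _inject_artifacts(mt, spec.artifact_fraction, rng)}

    return SlidePair(he_image=np.clip(np.round(he), 0, 255).astype(np.uint8),
                     mt_image=np.clip(np.round(mt), 0, 255).astype(np.uint8),
                     true_transform=transform, landmark_set=landmarks,
                     artifact_masks=masks, meta={"spec": asdict(spec)})


def _inject_artifacts(img: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Blank (white) rectangles and one dark fold band, in place.

    Returns the boolean mask of affected pixels.
    """
    h, w = img.shape[:2]
    affected = np.zeros((h, w), dtype=bool)
    if fraction <= 0:
        return affected
    target = fraction * h * w
    covered = 0.0
    while covered < 0.7 * target:
        rw = rng.integers(max(2, w // 20), max(3, w // 8))
        rh = rng.integers(max(2, h // 20), max(3, h // 8))
        x0 = rng.integers(0, w - rw)
        y0 = rng.integers(0, h - rh)
        img[y0:y0 + rh, x0:x0 + rw] = 255.0
        affected[y0:y0 + rh, x0:x0 + rw] = True
        covered += rw * rh
    # one fold: a dark band across a random chord, affecting tissue only
    # (a fold doubles section thickness; bare glass stays bright)
    x1, y1 = rng.uniform(0, w), rng.uniform(0, h)
    angle = rng.uniform(0, np.pi)
    n = np.array([np.sin(angle), -np.cos(angle)])
    ys, xs = np.mgrid[0:h, 0:w]
    dist = np.abs((xs - x1) * n[0] + (ys - y1) * n[1])
    band = dist < max(1.0, 0.3 * target / max(h, w))
    band &= img.mean(axis=-1) < 210
    img[band] *= 0.25
    affected |= band
    return affected


def tissue_mask(img: np.ndarray) -> np.ndarray:
    """Foreground (non-glass) mask of a rendered slide.

    Uses the same blur+Otsu pathway as slide tiling, so the mask is robust
    to per-slide stain-intensity jitter.
    """
    from .tiling import to_grayscale, gaussian_blur, otsu_threshold
    mask = otsu_threshold(gaussian_blur(to_grayscale(img), 2.0))
    return ~mask.binary if not mask.degenerate else np.zeros(img.shape[:2], bool)


DEFECT_LABELS = ("clean", "empty_heavy", "decorrelated", "hash_distant")


def generate_patch_set(pair: SlidePair, n: int, defect_rates: dict | None = None,
                       patch_size: int = 64, seed: int = 0) -> list:
    """Emit n aligned patch pairs with injected, labelled QC defects.

    The H&E slide is resampled through the ground-truth transform so that
    every window is perfectly co-located with its MT counterpart; defects
    are then injected per label:

    - ``empty_heavy``  — 40% of the pixels painted pure white on both sides
      (fails the empty rule only);
    - ``decorrelated`` — the MT side replaced by a deterministic oscillating
      remap of the H&E intensities: information-preserving (MI stays high)
      but angularly decorrelated (cosine forced below the keep threshold);
    - ``hash_distant`` — the MT side photometrically inverted: MI is
      invariant under the bijection and mid-tone cosine stays high, but the
      DCT hash bits flip.

    ``defect_rates`` maps defect label -> fraction of the n patches.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    defect_rates = defect_rates or {}
    unknown = set(defect_rates) - set(DEFECT_LABELS[1:])
    if unknown:
        raise ValueError(f"unknown defect labels: {sorted(unknown)}")
    from .qc import PatchPair

    rng = np.random.default_rng(seed)
    tf = pair.true_transform
    he = pair.he_image.astype(np.float64)
    if tf is None or tf.is_identity:
        he_aligned = he
    else:
        gy, gx = tf.grid_map()
        he_aligned = np.stack(
            [ndimage.map_coordinates(he[..., c], [gy, gx], order=1,
                                     mode="constant", cval=BACKGROUND)
             for c in range(he.shape[2])], axis=-1)
    mt = pair.mt_image.astype(np.float64)
    mask = tissue_mask(pair.mt_image)
    # windows must avoid slide artifacts: defect labels are sound only if
    # exactly the injected defect violates its rule
    avoid = pair.artifact_masks.get("mt", np.zeros(mt.shape[:2], bool)).copy()
    he_art = pair.artifact_masks.get("he")
    if he_art is not None and he_art.any() and tf is not None and not tf.is_identity:
        avoid |= ndimage.map_coordinates(he_art.astype(np.float64),
                                         [gy, gx], order=0) > 0
    elif he_art is not None:
        avoid |= he_art

    labels = []
    for lbl in DEFECT_LABELS[1:]:
        labels += [lbl] * round(defect_rates.get(lbl, 0.0) * n)
    labels += ["clean"] * (n - len(labels))
    rng.shuffle(labels)

    h, w = mt.shape[:2]
    out = []
    for lbl in labels[:n]:
        best, best_frac = None, -1.0
        for _ in range(200):
            x0 = int(rng.integers(0, w - patch_size))
            y0 = int(rng.integers(0, h - patch_size))
            if avoid[y0:y0 + patch_size, x0:x0 + patch_size].any():
                continue
            frac = mask[y0:y0 + patch_size, x0:x0 + patch_size].mean()
            if frac > best_frac:
                best, best_frac = (x0, y0), frac
            if frac >= 0.9:
                break
        if best is None:          # pathological artifact coverage
            best = (0, 0)
        x0, y0 = best
        hp = he_aligned[y0:y0 + patch_size, x0:x0 + patch_size].copy()
        mp = mt[y0:y0 + patch_size, x0:x0 + patch_size].copy()
        hp, mp = _inject_defect(lbl, hp, mp, rng)
        out.append(PatchPair(he_patch=np.clip(np.round(hp), 0, 255).astype(np.uint8),
                             mt_patch=np.clip(np.round(mp), 0, 255).astype(np.uint8),
                             coords=(x0, y0), label=lbl))
    return out


def _inject_defect(label: str, hp: np.ndarray, mp: np.ndarray,
                   rng: np.random.Generator):
    from .tiling import to_grayscale

    s = hp.shape[0]
    if label == "empty_heavy":
        # cover 40% of the area with pure white on both sides
        side = int(np.ceil(np.sqrt(0.4) * s))
        x0 = int(rng.integers(0, s - side + 1))
        y0 = int(rng.integers(0, s - side + 1))
        hp[y0:y0 + side, x0:x0 + side] = 255.0
        mp[y0:y0 + side, x0:x0 + side] = 255.0
    elif label == "decorrelated":
        # oscillating remap of the quantized H&E intensities: an exact
        # function of the 64-bin gray value (so MI stays at the entropy of
        # the bright/dark split, above the gate) but non-monotone with a
        # low-mean split, which drives the flattened-vector cosine far
        # below the keep threshold
        g = to_grayscale(hp)
        bins = np.clip((g / 256.0 * 64).astype(int), 0, 63)
        mass = np.bincount(bins.ravel(), minlength=64) / bins.size
        bright_bins = np.zeros(64, dtype=bool)
        bright_mass = cum = 0.0
        for b in np.nonzero(mass)[0]:          # greedy interleaving: keep the
            cum += mass[b]                     # running bright fraction <= 0.35
            if (bright_mass + mass[b]) / cum <= 0.35:
                bright_bins[b] = True
                bright_mass += mass[b]
        osc = np.where(bright_bins[bins], 235.0, 20.0)
        mp = np.repeat(osc[..., None], mp.shape[2], axis=2)
    elif label == "hash_distant":
        mp = 255.0 - mp
    elif label != "clean":
        raise ValueError(f"unknown defect label {label!r}")
    return hp, mp


def write_slide_pair(pair: SlidePair, outdir, stem: str = "pair") -> dict:
    """Write he/mt PNGs plus a JSON sidecar with transform and landmarks."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"he": outdir / f"{stem}_he.png", "mt": outdir / f"{stem}_mt.png",
             "sidecar": outdir / f"{stem}_transform.json"}
    iio.imwrite(paths["he"], pair.he_image)
    iio.imwrite(paths["mt"], pair.mt_image)
    side = {"true_transform": pair.true_transform.to_dict() if pair.true_transform else None,
            "landmarks": {"he": pair.landmark_set.he_points.tolist(),
                          "mt": pair.landmark_set.mt_points.tolist()}
            if pair.landmark_set else None,
            "meta": pair.meta}
    paths["sidecar"].write_text(json.dumps(side, indent=2))
    return paths
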