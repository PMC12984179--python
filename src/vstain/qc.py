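"""Patch-pair quality gating.

Consecutive-section H&E/MT patch pairs survive into training only if they
pass four checks, applied in a fixed order:

1. *empty*   — fraction of near-black or near-white pixels (blank glass,
   folds) must not exceed ``max_empty``;
2. *mi*      — histogram mutual information between the two stains must
   reach ``min_mi`` (statistical dependence despite different colors);
3. *cosine*  — cosine similarity of the flattened intensity vectors must
   reach ``min_cosine``;
4. *phash*   — Hamming distance of 64-bit DCT perceptual hashes must not
   exceed ``max_phash``.

Default thresholds (0.30, 0.35, 0.75, 20) are the ones the pipeline ships
with; the MI threshold is calibrated for base-2 logs over 64 histogram
bins, and both choices are recorded in every metadata record so the gate
is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.fft import dctn
from skimage.transform import resize

from .tiling import to_grayscale

__all__ = [
    "PatchPair",
    "QcScores",
    "QcThresholds",
    "empty_fraction",
    "histogram_mi",
    "cosine_similarity",
    "phash",
    "phash_distance",
    "qc_decide",
    "score_pair",
    "run_qc",
    "write_metadata",
]

#: 8-bit cutoffs defining "black" and "white" pixels for the empty check.
BLACK_CUT = 10
WHITE_CUT = 245

#: QC mutual-information convention: 64 bins, base-2 logs.
QC_MI_BINS = 64
QC_MI_BASE = 2.0

RULE_ORDER = ("empty", "mi", "cosine", "phash")


@dataclass
class QcScores:
    empty_fraction: float
    mi: float
    cosine: float
    phash_distance: int
    mi_bins: int = QC_MI_BINS
    mi_base: float = QC_MI_BASE


@dataclass
class QcThresholds:
    max_empty: float = 0.30
    min_mi: float = 0.35
    min_cosine: float = 0.75
    max_phash: int = 20


@dataclass
class PatchPair:
    """A co-located H&E/MT patch pair with provenance and QC state."""

    he_patch: np.ndarray
    mt_patch: np.ndarray
    coords: tuple[int, int] = (0, 0)
    transforms_applied: list = field(default_factory=list)
    qc: QcScores | None = None
    status: str = "pending"          # "kept" | "rejected:<reason>" | "pending"
    label: str | None = None         # fixture ground truth, if any


def _gray(patch: np.ndarray) -> np.ndarray:
    if patch.ndim == 3:
        return to_grayscale(patch)
    return np.asarray(patch, dtype=np.float64)


def empty_fraction(patch: np.ndarray, black_cut: int = BLACK_CUT,
                   white_cut: int = WHITE_CUT) -> float:
    """Fraction of pixels whose grayscale is <= black_cut or >= white_cut."""
    g = _gray(patch)
    return float(np.mean((g <= black_cut) | (g >= white_cut)))


def histogram_mi(a: np.ndarray, b: np.ndarray, n_bins: int = QC_MI_BINS,
                 base: float = QC_MI_BASE) -> float:
    """Plug-in mutual information ``H(X) + H(Y) - H(X, Y)`` from histograms.

    Intensities are binned into ``n_bins`` equal-width bins over [0, 255];
    entropies are plug-in estimates ``-sum p log p`` in the given log base.
    """
    ga, gb = _gray(a), _gray(b)
    if ga.shape != gb.shape:
        raise ValueError("images must share a shape")
    ia = np.clip((ga / 256.0 * n_bins).astype(int), 0, n_bins - 1)
    ib = np.clip((gb / 256.0 * n_bins).astype(int), 0, n_bins - 1)
    joint = np.bincount(ia.ravel() * n_bins + ib.ravel(),
                        minlength=n_bins * n_bins).astype(np.float64)
    joint /= joint.sum()
    px = joint.reshape(n_bins, n_bins).sum(axis=1)
    py = joint.reshape(n_bins, n_bins).sum(axis=0)

    def h(p):
        p = p[p > 0]
        return -np.sum(p * np.log(p))

    return float((h(px) + h(py) - h(joint)) / np.log(base))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between the flattened intensity vectors."""
    va = _gray(a).ravel()
    vb = _gray(b).ravel()
    if va.shape != vb.shape:
        raise ValueError("images must share a shape")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm image")
    return float(va @ vb / (na * nb))


def phash(patch: np.ndarray) -> np.ndarray:
    """64-bit DCT perceptual hash.

    Grayscale is resized to 32x32, a 2-D type-II DCT is taken, and the signs
    of the top-left 8x8 low-frequency block relative to its median give the
    64 hash bits.
    """
    g = _gray(patch)
    small = resize(g, (32, 32), anti_aliasing=True, preserve_range=True)
    coeffs = dctn(small, type=2, norm="ortho")[:8, :8]
    return (coeffs > np.median(coeffs)).ravel()


def phash_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between the perceptual hashes of two patches."""
    return int(np.sum(phash(a) != phash(b)))


def qc_decide(scores: QcScores, thr: QcThresholds | None = None) -> str:
    """Keep/discard decision; boundary values are inclusive on the keep side.

    The rejection reason is the first failing rule in the fixed order
    (empty, mi, cosine, phash).
    """
    thr = thr or QcThresholds()
    failures = {
        "empty": scores.empty_fraction > thr.max_empty,
        "mi": scores.mi < thr.min_mi,
        "cosine": scores.cosine < thr.min_cosine,
        "phash": scores.phash_distance > thr.max_phash,
    }
    for rule in RULE_ORDER:
        if failures[rule]:
            return f"rejected:{rule}"
    return "kept"


def score_pair(pair: PatchPair) -> QcScores:
    """Compute all four QC scores for a patch pair.

    The empty check is taken over both stains (a blank region on either
    slide disqualifies the pair); the similarity checks compare H&E to MT.
    """
    empty = max(empty_fraction(pair.he_patch), empty_fraction(pair.mt_patch))
    return QcScores(
        empty_fraction=empty,
        mi=histogram_mi(pair.he_patch, pair.mt_patch),
        cosine=cosine_similarity(pair.he_patch, pair.mt_patch),
        phash_distance=phash_distance(pair.he_patch, pair.mt_patch),
    )


def run_qc(pairs: list[PatchPair], thr: QcThresholds | None = None) -> list[PatchPair]:
    """Score and decide every pair in place; returns the same list."""
    thr = thr or QcThresholds()
    for p in pairs:
        p.qc = score_pair(p)
        p.status = qc_decide(p.qc, thr)
    return pairs


def write_metadata(pairs: list[PatchPair], path, thr: QcThresholds | None = None) -> None:
    """One JSON-lines record per patch: coords, scores, thresholds, status."""
    thr = thr or QcThresholds()
    with open(path, "w") as fh:
        for p in pairs:
            rec = {"coords": list(p.coords), "status": p.status,
                   "scores": asdict(p.qc) if p.qc else None,
                   "thresholds": asdict(thr)}
            fh.write(json.dumps(rec) + "\n")
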