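"""Reinhard color-transfer stain normalization.

Staining intensity varies slide to slide (reagent batches, section
thickness), which destabilizes stain-to-stain translation.  Reinhard's
method standardizes appearance by matching the per-channel mean and
standard deviation of an image to those of a reference image in the LAB
color space, where lightness is decorrelated from chroma.

The 8-bit-scaled LAB dialect is used: channels are notionally stored as
bytes (L in 0..255, A and B offset by +128) and rescaled so that
``L_n = L/2.55`` lies in [0, 100] and ``A_n = A - 128``, ``B_n = B - 128``
lie in [-128, 127].  The transfer acts on the rescaled channels and is
inverted symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import color

__all__ = ["LabStats", "rgb_to_lab_scaled", "lab_scaled_to_rgb", "lab_stats",
           "reinhard_transfer", "reinhard_transfer_lab",
           "normalize_to_reference"]

#: valid rescaled channel ranges, used for clipping before inversion
L_RANGE = (0.0, 100.0)
AB_RANGE = (-128.0, 127.0)


@dataclass
class LabStats:
    mu: tuple[float, float, float]
    sigma: tuple[float, float, float]
    degenerate: bool = False


def _split_alpha(img: np.ndarray):
    if img.ndim == 3 and img.shape[2] == 4:
        return img[..., :3], img[..., 3:]
    return img, None


def rgb_to_lab_scaled(img: np.ndarray) -> np.ndarray:
    """8-bit RGB -> LAB with L in [0, 100] and A, B in [-128, 127].

    The byte-stored representation (L*2.55, A+128, B+128) and its printed
    rescaling cancel for L and A/B alike, so the rescaled channels coincide
    with the standard D65 CIELAB values, clipped to the byte-representable
    ranges.
    """
    rgb, _ = _split_alpha(img)
    lab = color.rgb2lab(np.asarray(rgb, dtype=np.float64) / 255.0)
    lab[..., 0] = np.clip(lab[..., 0], *L_RANGE)
    lab[..., 1] = np.clip(lab[..., 1], *AB_RANGE)
    lab[..., 2] = np.clip(lab[..., 2], *AB_RANGE)
    return lab


def lab_scaled_to_rgb(lab: np.ndarray, quantize: bool = True) -> np.ndarray:
    """Inverse transform back to RGB.

    With ``quantize`` (the export path) values are rounded to 8 bits;
    otherwise float RGB on the 0-255 scale is returned, which preserves the
    transferred statistics exactly on low-variance channels.
    """
    rgb = np.clip(color.lab2rgb(lab), 0.0, 1.0) * 255.0
    if quantize:
        return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb


def lab_stats(lab: np.ndarray) -> LabStats:
    """Per-channel mean and population standard deviation over all pixels."""
    if lab.size == 0:
        raise ValueError("empty image")
    flat = lab.reshape(-1, lab.shape[-1])
    mu = flat.mean(axis=0)
    sigma = flat.std(axis=0)           # population convention (divide by N)
    return LabStats(mu=tuple(map(float, mu)), sigma=tuple(map(float, sigma)),
                    degenerate=bool(np.any(sigma == 0)))


def reinhard_transfer_lab(lab: np.ndarray, target_stats: LabStats,
                          source_stats: LabStats | None = None) -> np.ndarray:
    """The core per-channel transfer on a LAB raster.

    ``x_norm = (x - mu_src) / sigma_src * sigma_tgt + mu_tgt`` per channel,
    clipped to the valid LAB ranges.  This is the normalization proper; the
    RGB export additionally maps out-of-gamut colors back into sRGB, which
    can compress extreme chroma.
    """
    src = source_stats or lab_stats(lab)
    if src.degenerate:
        raise ValueError("constant LAB channel: transfer undefined")
    out = np.empty_like(lab)
    for c in range(3):
        out[..., c] = ((lab[..., c] - src.mu[c]) / src.sigma[c]
                       * target_stats.sigma[c] + target_stats.mu[c])
    out[..., 0] = np.clip(out[..., 0], *L_RANGE)
    out[..., 1] = np.clip(out[..., 1], *AB_RANGE)
    out[..., 2] = np.clip(out[..., 2], *AB_RANGE)
    return out


def reinhard_transfer(source: np.ndarray, target_stats: LabStats,
                      quantize: bool = True) -> np.ndarray:
    """Match the LAB mean/std of ``source`` to ``target_stats``.

    Per channel: ``x_norm = (x - mu_src) / sigma_src * sigma_tgt + mu_tgt``.
    Values are clipped to the valid channel ranges before the inverse
    conversion.  A source with any constant channel is passed through
    unchanged with a warning (the transfer is undefined there).  An alpha
    channel, if present, is carried through untouched.  ``quantize=False``
    keeps float RGB (no 8-bit rounding), matching the target statistics up
    to clipping only.
    """
    rgb, alpha = _split_alpha(source)
    lab = rgb_to_lab_scaled(rgb)
    src = lab_stats(lab)
    if src.degenerate:
        warnings.warn("constant LAB channel in source; Reinhard transfer skipped")
        return source.copy()
    out = reinhard_transfer_lab(lab, target_stats, src)
    result = lab_scaled_to_rgb(out, quantize=quantize)
    if alpha is not None:
        alpha = alpha.astype(result.dtype)
        result = np.concatenate([result, alpha], axis=-1)
    return result


def normalize_to_reference(source: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Convenience wrapper: transfer ``source`` onto ``reference``'s stats."""
    return reinhard_transfer(source, lab_stats(rgb_to_lab_scaled(reference)))
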