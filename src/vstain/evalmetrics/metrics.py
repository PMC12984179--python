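"""Image similarity/dissimilarity metric battery.

Generated virtual-MT tiles are compared against reference MT tiles with a
battery of full-reference metrics spanning information content (MI, NMI),
structure (SSIM, UQI, GMSD, phase congruency), correlation (NCC, cosine),
pixel error (MSE, NMSE, PSNR), histogram geometry (histogram intersection,
EMD, JSD, KLD, Hellinger, Bhattacharyya) and perceptual hashing.  Each
metric carries a direction (higher- or lower-is-better) used by the
reporting layer.

All metrics operate on 8-bit grayscale renderings of equal-shape images;
histogram metrics use normalized 256-bin histograms.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter, convolve
from skimage.metrics import structural_similarity

from ..qc import histogram_mi, cosine_similarity, phash_distance
from ..tiling import to_grayscale

__all__ = ["METRIC_DIRECTIONS", "DEFAULT_METRICS", "metric_battery"]

#: direction of improvement per metric
METRIC_DIRECTIONS = {
    "MI": "higher", "NMI": "higher", "SSIM": "higher", "NCC": "higher",
    "CS": "higher", "HistInt": "higher", "UQI": "higher", "PSNR": "higher",
    "PC": "higher", "NQM": "higher",
    "MSE": "lower", "NMSE": "lower", "EMD": "lower", "pHash": "lower",
    "JSD": "lower", "KLD": "lower", "GMSD": "lower", "HD": "lower",
    "BhD": "lower", "BRISQUE": "lower",
}

#: metrics computed by default (BRISQUE needs an external pretrained
#: natural-scene model; FBS/SRS have no established definition and are
#: excluded -- see the methods note)
DEFAULT_METRICS = ("MI", "NMI", "SSIM", "NCC", "CS", "HistInt", "UQI",
                   "PSNR", "MSE", "NMSE", "EMD", "pHash", "JSD", "KLD",
                   "GMSD", "HD", "BhD", "PC", "NQM")


def _gray(img):
    if img.ndim == 3:
        return to_grayscale(img)
    return np.asarray(img, dtype=np.float64)


def _hist(g, bins=256):
    h = np.bincount(np.clip(g.astype(int), 0, 255).ravel(), minlength=bins)
    return h / h.sum()


def _entropy(p):
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mi(x, y):
    return histogram_mi(x, y, n_bins=256, base=2.0)


def nmi(x, y):
    """MI normalized by the sum of marginal entropies (range [0, 0.5])."""
    hx = _entropy(_hist(_gray(x)))
    hy = _entropy(_hist(_gray(y)))
    if hx + hy == 0:
        return 0.0
    return mi(x, y) / (hx + hy)


def ssim(x, y):
    return float(structural_similarity(
        _gray(x), _gray(y), data_range=255.0, gaussian_weights=True,
        sigma=1.5, use_sample_covariance=False))


def ncc(x, y):
    gx, gy = _gray(x).ravel(), _gray(y).ravel()
    cx, cy = gx - gx.mean(), gy - gy.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    return float((cx * cy).sum() / denom) if denom else 0.0


def hist_intersection(x, y):
    return float(np.minimum(_hist(_gray(x)), _hist(_gray(y))).sum())


def uqi(x, y, window: int = 8):
    """Universal Quality Index averaged over a sliding window."""
    gx, gy = _gray(x), _gray(y)
    mx = uniform_filter(gx, window)
    my = uniform_filter(gy, window)
    sxx = uniform_filter(gx * gx, window) - mx * mx
    syy = uniform_filter(gy * gy, window) - my * my
    sxy = uniform_filter(gx * gy, window) - mx * my
    num = 4 * sxy * mx * my
    den = (sxx + syy) * (mx**2 + my**2)
    q = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 1.0)
    return float(q.mean())


def mse(x, y):
    d = _gray(x) - _gray(y)
    return float(np.mean(d * d))


def nmse(x, y):
    gx = _gray(x)
    den = float(np.mean(gx * gx))
    return mse(x, y) / den if den else 0.0


def psnr(x, y):
    m = mse(x, y)
    return float("inf") if m == 0 else float(10.0 * np.log10(255.0**2 / m))


def emd(x, y):
    """1-D earth mover's distance: L1 distance between histogram CDFs."""
    return float(np.abs(np.cumsum(_hist(_gray(x)) - _hist(_gray(y)))).sum())


def _kl(p, q, eps=1e-12):
    p = np.clip(p, eps, None)
    q = np.clip(q, eps, None)
    return float((p * np.log2(p / q)).sum())


def jsd(x, y):
    p, q = _hist(_gray(x)), _hist(_gray(y))
    m = 0.5 * (p + q)
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def kld(x, y):
    return _kl(_hist(_gray(x)), _hist(_gray(y)))


def gmsd(x, y, c: float = 170.0):
    """Gradient-magnitude similarity deviation (Prewitt, half-scale)."""
    gx = uniform_filter(_gray(x), 2)[::2, ::2]
    gy = uniform_filter(_gray(y), 2)[::2, ::2]
    px = np.array([[1, 0, -1], [1, 0, -1], [1, 0, -1]]) / 3.0
    gmx = np.hypot(convolve(gx, px), convolve(gx, px.T))
    gmy = np.hypot(convolve(gy, px), convolve(gy, px.T))
    gms = (2 * gmx * gmy + c) / (gmx**2 + gmy**2 + c)
    return float(gms.std())


def hellinger(x, y):
    p, q = _hist(_gray(x)), _hist(_gray(y))
    # (1/sqrt 2) L2 distance of sqrt-histograms == sqrt(1 - BC), but exact at 0
    return float(np.sqrt(0.5 * ((np.sqrt(p) - np.sqrt(q))**2).sum()))


def bhattacharyya(x, y):
    bc = float(np.sqrt(_hist(_gray(x)) * _hist(_gray(y))).sum())
    return float(-np.log(max(bc, 1e-12)))


def _phase_congruency_map(g, n_scales=3, n_orients=4, min_wl=6.0,
                          mult=2.1, sigma_f=0.55, eps=1e-4):
    """Minimal log-Gabor phase congruency map (sum over orientations)."""
    h, w = g.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    theta = np.arctan2(-fy, fx)
    F = np.fft.fft2(g)
    pc_sum = np.zeros((h, w))
    for o in range(n_orients):
        angle = o * np.pi / n_orients
        ds = np.cos(theta) * np.sin(angle) - np.sin(theta) * np.cos(angle)
        dc = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
        spread = np.exp(-(np.arctan2(ds, dc)**2) / (2 * (np.pi / n_orients)**2))
        energy_re = np.zeros((h, w))
        energy_im = np.zeros((h, w))
        amp_sum = np.zeros((h, w))
        for s in range(n_scales):
            wl = min_wl * mult**s
            log_gabor = np.exp(-(np.log(radius * wl))**2 / (2 * np.log(sigma_f)**2))
            log_gabor[0, 0] = 0.0
            resp = np.fft.ifft2(F * log_gabor * spread)
            energy_re += resp.real
            energy_im += resp.imag
            amp_sum += np.abs(resp)
        pc_sum += np.hypot(energy_re, energy_im) / (amp_sum + eps)
    return pc_sum / n_orients


def pc_similarity(x, y):
    """Correlation of phase-congruency maps (1 for identical images)."""
    px = _phase_congruency_map(_gray(x))
    py = _phase_congruency_map(_gray(y))
    cx, cy = px - px.mean(), py - py.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    return float((cx * cy).sum() / denom) if denom else 1.0


def _csf_weight(shape):
    """Radial contrast-sensitivity weighting (Mannos-Sakrison form)."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None] * h / 2.0
    fx = np.fft.fftfreq(w)[None, :] * w / 2.0
    f = np.hypot(fx, fy) / max(h, w) * 60.0     # nominal cycles/degree
    csf = 2.6 * (0.0192 + 0.114 * f) * np.exp(-(0.114 * f)**1.1)
    csf[0, 0] = csf.max()
    return csf


def nqm(x, y):
    """Visual-weighted SNR in dB (simplified noise-quality measure).

    The reference and test images are weighted in the frequency domain by a
    radial contrast-sensitivity function before the SNR is computed; this
    keeps the perceptual weighting of the literature measure without its
    full multi-band contrast-masking model.
    """
    gx, gy = _gray(x), _gray(y)
    csf = _csf_weight(gx.shape)
    fx = np.fft.ifft2(np.fft.fft2(gx) * csf).real
    fy_ = np.fft.ifft2(np.fft.fft2(gy) * csf).real
    noise = ((fx - fy_)**2).sum()
    if noise == 0:
        return float("inf")
    return float(10.0 * np.log10((fx**2).sum() / noise))


def brisque(x, y=None, scorer=None):
    """No-reference perceptual score, delegated to an external scorer.

    BRISQUE requires a model pretrained on natural-scene statistics; pass a
    callable via ``scorer`` to enable it.
    """
    if scorer is None:
        raise NotImplementedError("BRISQUE needs an external pretrained scorer")
    return float(scorer(x))


_REGISTRY = {
    "MI": mi, "NMI": nmi, "SSIM": ssim, "NCC": ncc, "CS": cosine_similarity,
    "HistInt": hist_intersection, "UQI": uqi, "PSNR": psnr, "MSE": mse,
    "NMSE": nmse, "EMD": emd, "pHash": phash_distance, "JSD": jsd,
    "KLD": kld, "GMSD": gmsd, "HD": hellinger, "BhD": bhattacharyya,
    "PC": pc_similarity, "NQM": nqm,
}


def metric_battery(generated: np.ndarray, reference: np.ndarray,
                   metrics: tuple[str, ...] = DEFAULT_METRICS) -> dict[str, float]:
    """Evaluate every requested metric on one generated/reference pair."""
    if generated.shape[:2] != reference.shape[:2]:
        raise ValueError("generated and reference images must share a shape")
    out = {}
    for name in metrics:
        if name not in _REGISTRY:
            raise KeyError(f"unknown metric {name!r}")
        out[name] = _REGISTRY[name](generated, reference)
    return out
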