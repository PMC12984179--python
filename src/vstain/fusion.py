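"""Weighted fusion of the four configuration outputs.

The four training configurations (original vs. Reinhard input, cycle- vs.
identity-emphasis) have complementary failure modes; their outputs are
combined by a fixed arithmetic mean ``Y_fused = 1/4 * sum_k Y_k``.
Non-default weights are accepted for weight-search experiments, but the
shipped default is the equal-weight solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FusionInput", "fuse", "fuse_arrays"]

CONFIG_LABELS = ("O/10/3", "O/3/10", "R/10/3", "R/3/10")


@dataclass
class FusionInput:
    #: config label -> raster, all the same shape
    outputs: dict
    weights: dict = field(default_factory=lambda: {k: 0.25 for k in CONFIG_LABELS})


def fuse_arrays(rasters, weights=None, quantize: bool = True) -> np.ndarray:
    """Pixelwise weighted sum of same-shape rasters.

    The sum is accumulated in floating point and quantized to 8 bits once at
    the end (round-half-even), so no intermediate rounding error stacks up.
    Weights must be nonnegative and sum to 1 within 1e-9.
    """
    rasters = [np.asarray(r, dtype=np.float64) for r in rasters]
    shapes = {r.shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"rasters differ in shape: {shapes}")
    if weights is None:
        weights = [1.0 / len(rasters)] * len(rasters)
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    acc = sum(w * r for w, r in zip(weights, rasters))
    if not quantize:
        return acc
    return np.clip(np.round(acc), 0, 255).astype(np.uint8)


def fuse(inp: FusionInput, quantize: bool = True) -> np.ndarray:
    """Fuse the four configuration outputs of a :class:`FusionInput`."""
    if set(inp.outputs) != set(inp.weights):
        raise ValueError("outputs and weights must share keys")
    keys = sorted(inp.outputs)
    return fuse_arrays([inp.outputs[k] for k in keys],
                       [inp.weights[k] for k in keys], quantize=quantize)
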