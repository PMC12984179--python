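"""Training orchestration, checkpointing and inference for the stain GAN.

Tiles enter as 8-bit rasters and are normalized to [-1, 1].  Training
alternates generator and discriminator updates with batch size 1 and
gradient accumulation over ``grad_accum_steps`` virtual batches; every
randomness source derives from the configured seed, so a repeated run is
bit-identical.  The four study configurations (original vs. normalized
input x cycle vs. identity emphasis) can be launched together and fused
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, Adam
from .model import TbGanHyperparams, GanConfig, Generator, Discriminator
from .losses import compute_losses, discriminator_loss, LossBreakdown

__all__ = ["TrainResult", "train", "train_all_configs", "infer",
           "save_checkpoint", "load_checkpoint", "to_unit", "from_unit"]


def to_unit(img: np.ndarray) -> np.ndarray:
    """8-bit raster -> float in [-1, 1]."""
    return np.asarray(img, dtype=np.float64) / 127.5 - 1.0


def from_unit(x: np.ndarray) -> np.ndarray:
    """[-1, 1] float -> 8-bit raster."""
    return np.clip(np.round((np.asarray(x) + 1.0) * 127.5), 0, 255).astype(np.uint8)


@dataclass
class TrainResult:
    config: GanConfig
    hyper: TbGanHyperparams
    G_A: Generator
    G_B: Generator
    D_A: Discriminator
    D_B: Discriminator
    loss_curve: list[LossBreakdown] = field(default_factory=list)
    d_loss_curve: list[float] = field(default_factory=list)

    @property
    def generator_totals(self) -> list[float]:
        return [b.total for b in self.loss_curve]


def _prep_batches(tiles, hyper) -> list[np.ndarray]:
    h, w, c = hyper.input_shape
    out = []
    for t in tiles:
        arr = np.asarray(t)
        if arr.ndim == 2:
            arr = arr[..., None]
        if arr.shape[2] < c:          # pad channels (e.g. RGB -> RGBA)
            alpha = np.full(arr.shape[:2] + (c - arr.shape[2],), 255, arr.dtype)
            arr = np.concatenate([arr, alpha], axis=-1)
        if arr.shape[:2] != (h, w):
            from skimage.transform import resize
            arr = resize(arr, (h, w), preserve_range=True, anti_aliasing=True)
        out.append(to_unit(arr)[None])   # batch axis
    return out


def train(config: GanConfig, tiles_A, tiles_B,
          hyper: TbGanHyperparams | None = None, n_steps: int = 50,
          normalize_fn=None) -> TrainResult:
    """Train one configuration for ``n_steps`` optimization steps.

    ``tiles_A`` are H&E tiles, ``tiles_B`` MT tiles (8-bit rasters).  For a
    Reinhard-input configuration the caller passes ``normalize_fn`` which is
    applied to every tile before training.  Loss curves log the per-step
    generator breakdown and discriminator loss.
    """
    hyper = hyper or TbGanHyperparams(lambda_cycle=config.lambdas[0],
                                      lambda_identity=config.lambdas[1])
    if not tiles_A or not tiles_B:
        raise ValueError("need at least one tile per domain")
    if config.input_variant == "reinhard" and normalize_fn is not None:
        tiles_A = [normalize_fn(t) for t in tiles_A]
        tiles_B = [normalize_fn(t) for t in tiles_B]
    batches_A = _prep_batches(tiles_A, hyper)
    batches_B = _prep_batches(tiles_B, hyper)

    rng = np.random.default_rng(hyper.seed)
    G_A = Generator(hyper, rng)
    G_B = Generator(hyper, rng)
    D_A = Discriminator(hyper, rng)
    D_B = Discriminator(hyper, rng)
    opt_G = Adam(G_A.params() + G_B.params(), lr=hyper.lr, betas=hyper.betas)
    opt_D = Adam(D_A.params() + D_B.params(), lr=hyper.lr, betas=hyper.betas)

    result = TrainResult(config=config, hyper=hyper, G_A=G_A, G_B=G_B,
                         D_A=D_A, D_B=D_B)
    accum = max(1, hyper.grad_accum_steps)
    for step in range(n_steps):
        xa = Tensor(batches_A[rng.integers(len(batches_A))])
        xb = Tensor(batches_B[rng.integers(len(batches_B))])

        # generator update (accumulated virtual batches)
        total, bd = compute_losses(xa, xb, G_A, G_B, D_A, D_B, config.lambdas)
        (total * (1.0 / accum)).backward()
        result.loss_curve.append(bd)
        if (step + 1) % accum == 0:
            opt_G.step()
            opt_G.zero_grad()

        # discriminator update on detached fakes
        fake_A = Tensor(G_A(xb).data)
        fake_B = Tensor(G_B(xa).data)
        d_loss = (discriminator_loss(D_A, xa, fake_A)
                  + discriminator_loss(D_B, xb, fake_B))
        (d_loss * (1.0 / accum)).backward()
        result.d_loss_curve.append(float(d_loss.data))
        if (step + 1) % accum == 0:
            opt_D.step()
            opt_D.zero_grad()
    return result


def train_all_configs(tiles_A, tiles_B, hyper_factory=None, n_steps: int = 50,
                      normalize_fn=None) -> dict[str, TrainResult]:
    """Train the four study configurations; returns label -> result."""
    out = {}
    for label in GanConfig.ALL_LABELS:
        cfg = GanConfig.from_label(label)
        hyper = (hyper_factory(cfg) if hyper_factory
                 else TbGanHyperparams(lambda_cycle=cfg.lambdas[0],
                                       lambda_identity=cfg.lambdas[1]))
        hyper.lambda_cycle, hyper.lambda_identity = cfg.lambdas
        out[label] = train(cfg, tiles_A, tiles_B, hyper, n_steps=n_steps,
                           normalize_fn=normalize_fn)
    return out


def infer(generator: Generator, tile: np.ndarray) -> np.ndarray:
    """Translate one H&E tile to a virtual MT tile.

    The tile is resized to the configured input shape if needed and
    normalized to [-1, 1]; the output is mapped back to 8 bits with any
    generated alpha channel discarded.  No registration is involved.
    """
    hyper = generator.hyper
    batch = _prep_batches([tile], hyper)[0]
    out = generator(Tensor(batch)).data[0]
    return from_unit(out)[..., :3]


def save_checkpoint(result: TrainResult, path) -> None:
    """Weights as .npz plus a JSON manifest next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, net in (("G_A", result.G_A), ("G_B", result.G_B),
                      ("D_A", result.D_A), ("D_B", result.D_B)):
        for i, p in enumerate(net.params()):
            arrays[f"{name}_{i}"] = p.data
    np.savez_compressed(path, **arrays)
    manifest = {"config": result.config.label,
                "hyper": asdict(result.hyper),
                "n_steps": len(result.loss_curve),
                "final_total": result.generator_totals[-1]
                if result.loss_curve else None}
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> TrainResult:
    manifest = json.loads(Path(str(path) + ".json").read_text())
    hyper_kwargs = manifest["hyper"]
    hyper_kwargs["input_shape"] = tuple(hyper_kwargs["input_shape"])
    hyper_kwargs["betas"] = tuple(hyper_kwargs["betas"])
    hyper = TbGanHyperparams(**hyper_kwargs)
    cfg = GanConfig.from_label(manifest["config"])
    rng = np.random.default_rng(hyper.seed)
    nets = {"G_A": Generator(hyper, rng), "G_B": Generator(hyper, rng),
            "D_A": Discriminator(hyper, rng), "D_B": Discriminator(hyper, rng)}
    data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
    for name, net in nets.items():
        for i, p in enumerate(net.params()):
            p.data = data[f"{name}_{i}"]
    return TrainResult(config=cfg, hyper=hyper, **nets)
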