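"""Cycle-GAN loss terms for unpaired stain translation.

Domain A is H&E, domain B is MT.  ``G_A : B -> A`` and ``G_B : A -> B`` are
the generators, ``D_A`` / ``D_B`` the discriminators of each domain.  The
training objective combines

- adversarial terms (cross-entropy between discriminator outputs and
  real/fake targets),
- L1 cycle-consistency ``|X - G_A(G_B(X))|`` and ``|Y - G_B(G_A(Y))|``,
- L1 identity terms ``|X - G_A(X)|`` and ``|Y - G_B(Y)|``,

into ``L_total = L_adv_A + L_adv_B + lambda_cycle (cyc_A + cyc_B)
+ lambda_identity (id_A + id_B)``.  By default the generator minimizes the
non-saturating form ``-log D(G(.))``; a flag restores the printed minimax
form ``log(1 - D(G(.)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autodiff import Tensor

__all__ = ["LossBreakdown", "compute_losses", "discriminator_loss"]

_EPS = 1e-7


@dataclass
class LossBreakdown:
    adv_A: float
    adv_B: float
    cycle_A: float
    cycle_B: float
    id_A: float
    id_B: float
    lambda_cycle: float
    lambda_identity: float

    @property
    def total(self) -> float:
        return (self.adv_A + self.adv_B
                + self.lambda_cycle * (self.cycle_A + self.cycle_B)
                + self.lambda_identity * (self.id_A + self.id_B))


def _log(x: Tensor) -> Tensor:
    return (x + _EPS).log()


def compute_losses(batch_A: Tensor, batch_B: Tensor, G_A, G_B, D_A, D_B,
                   lambdas: tuple[float, float], saturating: bool = False):
    """Generator-side loss graph and its logged breakdown.

    Returns ``(total, breakdown)`` where ``total`` is the scalar Tensor to
    backpropagate and ``breakdown`` the float record whose recomposed total
    equals ``total`` exactly.
    """
    lam_cycle, lam_id = lambdas
    fake_A = G_A(batch_B)
    fake_B = G_B(batch_A)
    if saturating:
        adv_A = _log(1.0 - D_A(fake_A)).mean()
        adv_B = _log(1.0 - D_B(fake_B)).mean()
    else:
        adv_A = -(_log(D_A(fake_A)).mean())
        adv_B = -(_log(D_B(fake_B)).mean())
    cyc_A = (batch_A - G_A(fake_B)).abs().mean()
    cyc_B = (batch_B - G_B(fake_A)).abs().mean()
    id_A = (batch_A - G_A(batch_A)).abs().mean()
    id_B = (batch_B - G_B(batch_B)).abs().mean()
    total = (adv_A + adv_B + lam_cycle * (cyc_A + cyc_B)
             + lam_id * (id_A + id_B))
    if not float(total.data).__eq__(float(total.data)):   # NaN guard
        raise FloatingPointError("non-finite generator loss")
    bd = LossBreakdown(adv_A=float(adv_A.data), adv_B=float(adv_B.data),
                       cycle_A=float(cyc_A.data), cycle_B=float(cyc_B.data),
                       id_A=float(id_A.data), id_B=float(id_B.data),
                       lambda_cycle=lam_cycle, lambda_identity=lam_id)
    return total, bd


def discriminator_loss(D, real: Tensor, fake: Tensor) -> Tensor:
    """Binary cross-entropy of one discriminator on a real/fake pair.

    ``fake`` must be detached from the generator graph by the caller.
    """
    loss_real = -(_log(D(real)).mean())
    loss_fake = -(_log(1.0 - D(fake)).mean())
    return (loss_real + loss_fake) * 0.5
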