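"""Training loss terms.

Three families of terms drive training:

* reconstruction (per path i -> j, computed batchwise in reduced space):
  ``L_r.mse`` (elementwise MSE, weight ``w_rm``), ``L_r.corrI`` (squared
  deviation of the batchwise predicted-vs-true cross-correlation matrix from
  identity) and ``L_r.marg`` (a contrastive margin on the same matrix: every
  off-diagonal correlation must trail the subject's own diagonal by at least
  ``recon_margin``);
* latent dispersion (per path, on the encoded batch z): ``L_z.corrI``
  (cosine-similarity matrix vs identity) and ``L_z.dist`` (a margin pushing
  pairwise latent distances above ``latent_margin``), jointly weighted by
  ``w_z``;
* latent consistency (across flavors, full cohort): ``L_z.sim`` — summed
  MSE between the latent matrices of every flavor pair, weighted ``w_zs``.

Every term is written against :mod:`conncodec.autodiff`, so the same code
evaluates plain arrays (for oracles/monitoring) and differentiable Tensors
(for training). The exact algebraic forms of the correlation/margin terms
are committed package defaults, registered by name so alternates can be
swapped without touching the trainer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .flavors import ValidationError

__all__ = ["LossWeights", "loss_recon", "loss_latent_dispersion",
           "loss_latent_consistency", "RECON_TERMS", "LATENT_TERMS"]

_EPS = 1e-12


@dataclass
class LossWeights:
    """Loss weights and margins (defaults follow the trained reference model)."""

    w_rm: float = 1000.0       # reconstruction MSE weight
    w_z: float = 10.0          # path-wise latent dispersion weight
    w_zs: float = 10000.0      # latent intra-subject consistency weight
    recon_margin: float = 0.1
    latent_margin: float = 1.0

    def __post_init__(self):
        for name in ("w_rm", "w_z", "w_zs", "recon_margin", "latent_margin"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _batch_size(x) -> int:
    return ad.value_of(x).shape[0]


def _row_corr_matrix(P, T):
    """C[a, b] = Pearson corr of row a of P with row b of T (autodiff-safe)."""
    n = _batch_size(P)
    Pc = P - ad.mean(P, axis=1, keepdims=True)
    Tc = T - ad.mean(T, axis=1, keepdims=True)
    Pn = Pc * (ad.sqrt(ad.sum_(Pc * Pc, axis=1, keepdims=True) + _EPS) ** -1.0)
    Tn = Tc * (ad.sqrt(ad.sum_(Tc * Tc, axis=1, keepdims=True) + _EPS) ** -1.0)
    return ad.matmul(Pn, ad.transpose(Tn))


def _mse_term(pred, true):
    d = pred - true
    return ad.mean(d * d)


def _corr_identity_term(C, n: int):
    eye = np.eye(n)
    d = C - eye
    return ad.mean(d * d)


def _recon_margin_term(C, n: int, margin: float):
    """Mean over ordered pairs a != b of relu(margin - (C_aa - C_ab))^2."""
    diag = ad.sum_(C * np.eye(n), axis=1, keepdims=True)  # (n,1) diagonal
    gap = diag - C                                        # C_aa - C_ab
    h = ad.relu(margin - gap)
    off = 1.0 - np.eye(n)
    return ad.sum_(h * h * off) * (1.0 / (n * (n - 1)))


def loss_recon(x_true, x_pred, weights: LossWeights):
    """Path-wise reconstruction + reconstruction-space dispersion loss.

    Returns ``(total, breakdown)`` where total = w_rm * L_r.mse + L_r.corrI
    + L_r.marg and breakdown holds the unweighted terms as floats.
    """
    n = _batch_size(x_true)
    if n < 2:
        raise ValidationError("reconstruction dispersion needs a batch of >= 2")
    if ad.value_of(x_true).shape != ad.value_of(x_pred).shape:
        raise ValidationError("true/predicted batch shapes differ")
    sd = ad.value_of(x_true).std(axis=1)
    if np.any(sd < 1e-14):
        import warnings
        warnings.warn("zero-variance subject rows in batch: correlation terms "
                      "are eps-guarded")
    mse = _mse_term(x_pred, x_true)
    C = _row_corr_matrix(x_pred, x_true)
    corrI = _corr_identity_term(C, n)
    marg = _recon_margin_term(C, n, weights.recon_margin)
    total = weights.w_rm * mse + corrI + marg
    breakdown = {"r.mse": float(ad.value_of(mse)),
                 "r.corrI": float(ad.value_of(corrI)),
                 "r.marg": float(ad.value_of(marg))}
    return total, breakdown


def _pairwise_distance_matrix(z, n: int):
    """D[a, b] = ||z_a - z_b||, eps-guarded at the diagonal."""
    k = ad.value_of(z).shape[1]
    za = ad.reshape(z, (n, 1, k))
    zb = ad.reshape(z, (1, n, k))
    d = za - zb
    return ad.sqrt(ad.sum_(d * d, axis=2) + _EPS)


def loss_latent_dispersion(z, weights: LossWeights):
    """Path-wise latent dispersion: w_z * (L_z.corrI + L_z.dist).

    ``z`` must be a batch of unit-norm latent rows. L_z.corrI measures the
    cosine-similarity matrix's deviation from identity; L_z.dist penalizes
    pairs closer than ``latent_margin``.
    """
    n = _batch_size(z)
    if n < 2:
        raise ValidationError("latent dispersion needs a batch of >= 2")
    S = ad.matmul(z, ad.transpose(z))  # cosine similarity (unit rows)
    corrI = _corr_identity_term(S, n)
    D = _pairwise_distance_matrix(z, n)
    h = ad.relu(weights.latent_margin - D)
    off = 1.0 - np.eye(n)
    dist = ad.sum_(h * h * off) * (1.0 / (n * (n - 1)))
    total = weights.w_z * (corrI + dist)
    breakdown = {"z.corrI": float(ad.value_of(corrI)),
                 "z.dist": float(ad.value_of(dist))}
    return total, breakdown


def loss_latent_consistency(z_by_flavor, weights: LossWeights):
    """Cross-flavor latent consistency: w_zs * sum_{i<j} MSE(z_i, z_j).

    ``z_by_flavor`` is an ordered mapping or list of latent matrices with
    aligned subject rows.
    """
    if isinstance(z_by_flavor, dict):
        zs = list(z_by_flavor.values())
    else:
        zs = list(z_by_flavor)
    if len(zs) < 2:
        raise ValidationError("latent consistency needs >= 2 flavors")
    shapes = {ad.value_of(z).shape for z in zs}
    if len(shapes) != 1:
        raise ValidationError("flavor latent matrices are misaligned")
    total = None
    for i in range(len(zs)):
        for j in range(i + 1, len(zs)):
            term = _mse_term(zs[i], zs[j])
            total = term if total is None else total + term
    total = weights.w_zs * total
    return total, {"z.sim": float(ad.value_of(total)) / max(weights.w_zs, _EPS)}


RECON_TERMS = {"default": loss_recon}
LATENT_TERMS = {"default": loss_latent_dispersion}
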