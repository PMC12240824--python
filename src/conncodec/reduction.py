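"""Per-flavor fixed PCA dimensionality reduction.

Each connectome flavor is reduced from its native edge dimension (3k-96k
edges at full scale) to a common small dimension (256 by default) with a
PCA basis fitted on training subjects only. Scores are whitened — divided
by the per-component training standard deviation — so that disparate
flavors contribute comparably to the shared latent space. The transform is
affine and exactly invertible on its subspace, which is how predictions made
in reduced space are returned to native edge dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .flavors import EdgeVectorSet, FlavorSpec, ValidationError

__all__ = ["ReductionModel", "fit_reduction", "reduce", "restore"]

_SCALE_FLOOR = 1e-12


@dataclass
class ReductionModel:
    """Training mean + orthonormal component basis + per-component scale."""

    flavor: FlavorSpec
    train_mean: np.ndarray            # (n_edges,)
    components: np.ndarray            # (n_comp, n_edges), orthonormal rows
    component_scale: np.ndarray       # (n_comp,), training std of each score
    whiten: bool = True

    @property
    def n_comp(self) -> int:
        return self.components.shape[0]

    def __post_init__(self):
        k = self.components.shape[0]
        gram = self.components @ self.components.T
        if np.max(np.abs(gram - np.eye(k))) > 1e-6:
            raise ValidationError("reduction components are not orthonormal")


def fit_reduction(train: EdgeVectorSet, n_comp: int = 256,
                  whiten: bool = True) -> ReductionModel:
    """Fit the fixed PCA reduction on training subjects.

    Deterministic: component signs are fixed so the largest-magnitude
    loading of each component is positive. If fewer than ``n_comp + 1``
    training subjects (or ``n_comp`` exceeds the edge count), ``n_comp`` is
    lowered with a warning so small cohorts remain usable.
    """
    X = train.data
    n_train, n_edges = X.shape
    if n_comp > n_edges:
        raise ValidationError(
            f"n_comp={n_comp} exceeds edge dimension {n_edges} for flavor "
            f"{train.flavor.name}")
    k = min(int(n_comp), n_train - 1, n_edges)
    if k < n_comp:
        warnings.warn(
            f"{train.flavor.name}: lowering n_comp from {n_comp} to {k} "
            f"(n_train={n_train}, n_edges={n_edges})")
    if k < 1:
        raise ValidationError("need at least 2 training subjects to fit a reduction")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of centered data; rows of Vt are principal axes
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = Vt[:k].copy()
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    scores = Xc @ comps.T
    scale = scores.std(axis=0, ddof=0)
    scale = np.maximum(scale, _SCALE_FLOOR)
    return ReductionModel(train.flavor, mean, comps, scale, whiten=whiten)


def reduce(x: np.ndarray | EdgeVectorSet, r: ReductionModel) -> np.ndarray:
    """Project edge vectors into the reduced (whitened-score) space."""
    X = x.data if isinstance(x, EdgeVectorSet) else np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != r.train_mean.size:
        raise ValidationError(
            f"edge dimension {X.shape[1]} does not match reduction "
            f"({r.train_mean.size})")
    scores = (X - r.train_mean) @ r.components.T
    if r.whiten:
        scores = scores / r.component_scale
    return scores[0] if single else scores


def restore(xr: np.ndarray, r: ReductionModel) -> np.ndarray:
    """Map reduced vectors back to native edge dimensions (inverse of reduce)."""
    Xr = np.asarray(xr, dtype=float)
    single = Xr.ndim == 1
    Xr = np.atleast_2d(Xr)
    if Xr.shape[1] != r.n_comp:
        raise ValidationError(
            f"reduced dimension {Xr.shape[1]} does not match n_comp={r.n_comp}")
    scores = Xr * r.component_scale if r.whiten else Xr
    out = scores @ r.components + r.train_mean
    return out[0] if single else out
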