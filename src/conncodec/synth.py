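"""Synthetic multi-flavor connectome cohorts with known ground truth.

The generator emulates the structure the model assumes in real data: every
subject has a low-dimensional latent "connectomic backbone" u_s on the unit
sphere; each connectome flavor observes an affine image of (part of) that
backbone plus flavor-specific noise. Family members share correlated
latents (MZ > DZ >= sibling), age and sex shift designated latent
directions, cognition composites are linear readouts of the latent, and
retest sessions re-draw only the measurement noise. Functional flavors are
squashed into [-1, 1] around a base correlation template with tanh;
structural flavors are exponentiated to nonnegative pseudo-counts.

Because the ground truth is recorded, recovery experiments are exact: with
zero noise and full cross-modality overlap each flavor is (optionally) an
exact affine function of u_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flavors import (CohortTable, EdgeVectorSet, FlavorSpec, ValidationError,
                      count_edges)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort",
           "generate_timeseries", "default_desk_spec"]


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic cohort."""

    n_subj: int = 250
    flavors: list[FlavorSpec] = field(default_factory=list)
    latent_dim: int = 16
    overlap: float = 0.7            # cross-modality latent sharing fraction
    noise_sd: float | dict = 0.2    # per-flavor edge noise sd (scalar or by name)
    n_mz: int = 30
    n_dz: int = 20
    n_sib: int = 30
    rho_mz: float = 0.85
    rho_dz: float = 0.5
    rho_sib: float = 0.45
    age_range: tuple = (22.0, 37.0)
    age_effect: float = 0.4         # latent shift per sd of age
    sex_effect: float = 0.4
    cog_noise_sd: float = 0.3
    n_retest: int = 20
    retest_noise_sd: float | None = None   # default: same as noise_sd
    n_train: int = 200
    n_val: int = 20
    n_test: int = 30
    fc_squash: str = "tanh"         # "tanh" or "none" (exact affine data)
    sc_squash: str = "exp"          # "exp" or "none"
    seed: int = 12345

    def __post_init__(self):
        if not (self.rho_mz > self.rho_dz >= self.rho_sib > 0):
            raise ValidationError("need rho_MZ > rho_DZ >= rho_sib > 0")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValidationError("overlap fraction must be in [0, 1]")
        sds = (list(self.noise_sd.values())
               if isinstance(self.noise_sd, dict) else [self.noise_sd])
        if any(s < 0 for s in sds):
            raise ValidationError("noise sds must be >= 0")
        if self.n_train + self.n_val + self.n_test != self.n_subj:
            raise ValidationError("splits must partition n_subj")
        n_paired = 2 * (self.n_mz + self.n_dz + self.n_sib)
        if n_paired > self.n_subj:
            raise ValidationError("too many family pairs for n_subj")

    def noise_for(self, flavor: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd[flavor])
        return float(self.noise_sd)


@dataclass
class GroundTruth:
    """Everything the generator drew, for recovery experiments."""

    latents: np.ndarray                       # n_subj x d (unit rows)
    mixing: dict[str, np.ndarray]             # flavor -> n_edges x d_active
    active_dims: dict[str, np.ndarray]        # flavor -> latent dim indices
    offsets: dict[str, np.ndarray]            # flavor -> base edge template
    cog_loadings: np.ndarray                  # d x 4
    seed: int = 0


def _unit_rows(X: np.ndarray) -> np.ndarray:
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def _family_pairs(spec: SyntheticSpec) -> list[tuple[str, float]]:
    return ([("MZ", spec.rho_mz)] * spec.n_mz
            + [("DZ", spec.rho_dz)] * spec.n_dz
            + [("sibling", spec.rho_sib)] * spec.n_sib)


def _assign_pairs_to_splits(spec: SyntheticSpec) -> dict[str, list[int]]:
    """Deterministically allocate family pairs across splits.

    Pairs never span splits (both members share one split); allocation is
    proportional to split sizes, remainders to train.
    """
    pairs = _family_pairs(spec)
    n_pairs = len(pairs)
    sizes = {"train": spec.n_train, "val": spec.n_val, "test": spec.n_test}
    alloc = {}
    remaining = n_pairs
    for name in ("val", "test"):
        k = min(int(round(n_pairs * sizes[name] / spec.n_subj)), sizes[name] // 2)
        alloc[name] = k
        remaining -= k
    alloc["train"] = remaining
    if 2 * alloc["train"] > sizes["train"]:
        raise ValidationError("train split too small for the family pairs")
    out, i = {}, 0
    for name in ("train", "val", "test"):
        out[name] = list(range(i, i + alloc[name]))
        i += alloc[name]
    return out


def generate_cohort(spec: SyntheticSpec):
    """Generate edge data for all flavors plus cohort table and ground truth.

    Returns ``(edge_sets, cohort, truth)`` where ``edge_sets`` maps flavor
    name -> EdgeVectorSet (retest sessions appended as extra rows with ids
    ``<subject>_r2``).
    """
    if not spec.flavors:
        raise ValidationError("spec has no flavors")
    d = spec.latent_dim
    for fl in spec.flavors:
        if d > fl.n_edges:
            raise ValidationError(
                f"latent_dim {d} exceeds n_edges of flavor {fl.name}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subj
    ids = [f"sub{i:04d}" for i in range(n)]

    # --- family structure: convex mixing with a shared family vector -------
    pairs = _family_pairs(spec)
    pair_split = _assign_pairs_to_splits(spec)
    split_members = {"train": [], "val": [], "test": []}
    order = []
    for name in ("train", "val", "test"):
        size = {"train": spec.n_train, "val": spec.n_val, "test": spec.n_test}[name]
        order.extend([name] * size)
    latents = np.zeros((n, d))
    family_id = np.array([""] * n, dtype=object)
    zygosity = np.array(["none"] * n, dtype=object)
    split_col = np.array(order, dtype=object)

    # position cursors per split (pairs occupy the first slots of each split)
    split_start = {"train": 0, "val": spec.n_train,
                   "test": spec.n_train + spec.n_val}
    cursor = dict(split_start)
    fam_counter = 0
    pair_rows = []
    for name in ("train", "val", "test"):
        for pi in pair_split[name]:
            relation, rho = pairs[pi]
            f = rng.standard_normal(d)
            f /= np.linalg.norm(f)
            a = np.sqrt(rho)
            b = np.sqrt(1.0 - rho)
            i1, i2 = cursor[name], cursor[name] + 1
            cursor[name] += 2
            for i in (i1, i2):
                e = rng.standard_normal(d)
                e /= np.linalg.norm(e)
                latents[i] = a * f + b * e
            fam = f"fam{fam_counter:03d}"
            fam_counter += 1
            family_id[[i1, i2]] = fam
            zygosity[[i1, i2]] = relation
            pair_rows.append((ids[i1], ids[i2], relation))
            split_members[name].extend([i1, i2])
    # singletons
    for name in ("train", "val", "test"):
        size = {"train": spec.n_train, "val": spec.n_val, "test": spec.n_test}[name]
        while cursor[name] < split_start[name] + size:
            i = cursor[name]
            cursor[name] += 1
            e = rng.standard_normal(d)
            latents[i] = e / np.linalg.norm(e)
            family_id[i] = f"fam{fam_counter:03d}"
            fam_counter += 1
    latents = _unit_rows(latents)

    # --- demographics shift designated latent directions --------------------
    age = rng.uniform(*spec.age_range, size=n)
    sex = rng.integers(0, 2, size=n)          # 0 = F, 1 = M
    z_age = (age - age.mean()) / age.std()
    latents[:, 0] += spec.age_effect * z_age
    latents[:, 1 % d] += spec.sex_effect * (2.0 * sex - 1.0)
    latents = _unit_rows(latents)

    # cognition composites: linear readout of the latent + noise
    cog_load = rng.standard_normal((d, 4))
    cog_load /= np.linalg.norm(cog_load, axis=0)
    cog = latents @ cog_load + spec.cog_noise_sd * rng.standard_normal((n, 4))

    # --- modality-specific latent subspaces ---------------------------------
    n_shared = int(round(spec.overlap * d))
    private = np.arange(n_shared, d)
    half = private.size // 2
    fc_dims = np.concatenate([np.arange(n_shared), private[:half]]).astype(int)
    sc_dims = np.concatenate([np.arange(n_shared), private[half:]]).astype(int)

    # --- per-flavor affine maps + squashing ---------------------------------
    edge_sets: dict[str, EdgeVectorSet] = {}
    mixing, offsets, active = {}, {}, {}
    retest_idx = np.arange(min(spec.n_retest, spec.n_train))  # first train subjects
    retest_ids = [f"{ids[i]}_r2" for i in retest_idx]
    retest_sd = (spec.retest_noise_sd if spec.retest_noise_sd is not None
                 else None)
    for fl in spec.flavors:
        ne = fl.n_edges
        dims = fc_dims if fl.modality == "FC" else sc_dims
        da = dims.size
        W = rng.standard_normal((ne, da)) / np.sqrt(da)
        u_act = latents[:, dims]
        signal = u_act @ W.T * np.sqrt(da)    # unit-ish variance per edge
        sd = spec.noise_for(fl.name)
        noise = sd * rng.standard_normal((n, ne))
        r_sd = sd if retest_sd is None else retest_sd
        noise_rt = r_sd * rng.standard_normal((retest_idx.size, ne))
        if fl.modality == "FC":
            base = np.arctanh(np.clip(rng.uniform(-0.6, 0.6, size=ne), -0.999, 0.999))
            lin = base + 0.5 * (signal + noise)
            lin_rt = base + 0.5 * (signal[retest_idx] + noise_rt)
            if spec.fc_squash == "tanh":
                data, data_rt = np.tanh(lin), np.tanh(lin_rt)
            else:
                data, data_rt = lin, lin_rt
        else:
            base = rng.normal(0.0, 1.0, size=ne)
            lin = base + 0.5 * (signal + noise)
            lin_rt = base + 0.5 * (signal[retest_idx] + noise_rt)
            if spec.sc_squash == "exp":
                data, data_rt = np.exp(lin), np.exp(lin_rt)
            else:
                data, data_rt = lin, lin_rt
        edge_sets[fl.name] = EdgeVectorSet(
            fl, ids + retest_ids, np.vstack([data, data_rt]))
        mixing[fl.name] = W
        offsets[fl.name] = base
        active[fl.name] = dims

    # --- cohort table --------------------------------------------------------
    rows = []
    for i in range(n):
        rows.append(dict(subject_id=ids[i], age=age[i], sex="M" if sex[i] else "F",
                         cog_total=cog[i, 0], cog_fluid=cog[i, 1],
                         cog_cryst=cog[i, 2], cog_early=cog[i, 3],
                         family_id=family_id[i], zygosity=zygosity[i],
                         split=split_col[i], retest_of=""))
    for k, i in enumerate(retest_idx):
        rows.append(dict(subject_id=retest_ids[k], age=age[i],
                         sex="M" if sex[i] else "F",
                         cog_total=cog[i, 0], cog_fluid=cog[i, 1],
                         cog_cryst=cog[i, 2], cog_early=cog[i, 3],
                         family_id=family_id[i], zygosity=zygosity[i],
                         split=split_col[i], retest_of=ids[i]))
    cohort = CohortTable(pd.DataFrame(rows))
    truth = GroundTruth(latents=latents, mixing=mixing, active_dims=active,
                        offsets=offsets, cog_loadings=cog_load, seed=spec.seed)
    return edge_sets, cohort, truth


def generate_timeseries(cov: np.ndarray, T: int, seed: int = 0,
                        subject_id: str = "sim", atlas: str = "sim",
                        sampling_interval: float = 1.0):
    """Multivariate normal time series with a target covariance.

    Non-PSD targets are projected to the nearest PSD matrix (eigenvalue
    clipping) with a warning. Empirical FC converges to the target
    correlation as T grows.
    """
    import warnings as _w

    from .fc import RegionalTimeseries

    C = np.asarray(cov, dtype=float)
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-10:
        _w.warn("covariance target not PSD: clipping negative eigenvalues")
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, C.shape[0])) @ A.T
    return RegionalTimeseries(subject_id, atlas, X,
                              sampling_interval=sampling_interval)


def default_desk_spec(seed: int = 12345) -> SyntheticSpec:
    """The canonical desk-scale cohort: 2 atlases x (2 FC + 1 SC) = 6 flavors,
    250 subjects (200/20/30 train/val/test), 16 latent dims, overlap 0.7,
    30 MZ + 20 DZ + 30 sibling pairs, retest sessions for 20 subjects."""
    flavors = []
    for atlas, nr in (("A16", 16), ("B32", 32)):
        flavors += [
            FlavorSpec(f"{atlas}_FC", "FC", atlas, nr, fc_variant="pearson"),
            FlavorSpec(f"{atlas}_FCpcorr", "FC", atlas, nr, fc_variant="pcorr"),
            FlavorSpec(f"{atlas}_SCpr", "SC", atlas, nr, sc_variant="prob"),
        ]
    return SyntheticSpec(flavors=flavors, seed=seed)
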