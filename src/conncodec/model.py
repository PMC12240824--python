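"""The codec model: per-flavor linear encoders/decoders through a shared
unit-hypersphere latent space.

Each flavor *i* has a single fully connected encoder that maps its reduced
representation X'_i to a latent vector, followed by L2 normalization onto the
surface of a (by default) 128-dimensional hypersphere, and a single fully
connected decoder mapping latent vectors back to reduced space. Translating
flavor *i* to flavor *j* composes reduce_i -> encode_i -> decode_j ->
restore_j. Fusion averages a subject's latent vectors over a chosen subset of
flavors before decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field  # noqa: F401

import h5py
import numpy as np

from . import autodiff as ad
from .flavors import EdgeVectorSet, FlavorSpec, ValidationError
from .reduction import ReductionModel, reduce, restore

__all__ = [
    "FlavorCodec", "CodecModel", "LatentMatrix",
    "encode", "decode", "predict_path", "fuse", "fusion_subset",
    "adapt_population_mean", "latent_similarity",
    "save_model", "load_model",
]

_NORM_FLOOR = 1e-12
CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class FlavorCodec:
    """Encoder/decoder weights for one flavor."""

    flavor: FlavorSpec
    encoder_weight: np.ndarray   # (latent_dim, n_comp)
    encoder_bias: np.ndarray     # (latent_dim,)
    decoder_weight: np.ndarray   # (n_comp, latent_dim)
    decoder_bias: np.ndarray     # (n_comp,)

    def __post_init__(self):
        ld, nc = self.encoder_weight.shape
        if self.encoder_bias.shape != (ld,):
            raise ValidationError(f"{self.flavor.name}: encoder bias shape mismatch")
        if self.decoder_weight.shape != (nc, ld):
            raise ValidationError(f"{self.flavor.name}: decoder weight shape mismatch")
        if self.decoder_bias.shape != (nc,):
            raise ValidationError(f"{self.flavor.name}: decoder bias shape mismatch")

    @property
    def latent_dim(self) -> int:
        return self.encoder_weight.shape[0]

    @property
    def n_comp(self) -> int:
        return self.encoder_weight.shape[1]


def init_codec(flavor: FlavorSpec, n_comp: int, latent_dim: int,
               rng: np.random.Generator) -> FlavorCodec:
    """Random initialization (uniform +-1/sqrt(fan_in), zero biases)."""
    be = 1.0 / np.sqrt(n_comp)
    bd = 1.0 / np.sqrt(latent_dim)
    return FlavorCodec(
        flavor,
        rng.uniform(-be, be, size=(latent_dim, n_comp)),
        np.zeros(latent_dim),
        rng.uniform(-bd, bd, size=(n_comp, latent_dim)),
        np.zeros(n_comp),
    )


@dataclass
class LatentMatrix:
    """Subjects x latent_dim embeddings, from one flavor or a fusion."""

    subject_ids: list[str]
    data: np.ndarray
    source: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.subject_ids):
            raise ValidationError("latent rows do not match subject_ids")


@dataclass
class CodecModel:
    """Full set of flavor codecs sharing one latent convention."""

    flavors: list[FlavorSpec]
    reductions: dict[str, ReductionModel]
    codecs: dict[str, FlavorCodec]
    latent_dim: int = 128
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        for fl in self.flavors:
            if fl.name not in self.reductions or fl.name not in self.codecs:
                raise ValidationError(f"flavor {fl.name} missing reduction or codec")
            if self.codecs[fl.name].latent_dim != self.latent_dim:
                raise ValidationError(f"flavor {fl.name} codec latent_dim mismatch")

    def flavor(self, name: str) -> FlavorSpec:
        for fl in self.flavors:
            if fl.name == name:
                return fl
        raise KeyError(f"unknown flavor {name!r}")

    def encode_edges(self, x: EdgeVectorSet, flavor: str | None = None) -> LatentMatrix:
        """Edge vectors -> unit-norm latent rows for one flavor."""
        name = flavor or x.flavor.name
        xr = reduce(x.data, self.reductions[name])
        z = encode(xr, self.codecs[name])
        return LatentMatrix(list(x.subject_ids), z, source=name)


def _l2_normalize_rows(y):
    norms = ad.sqrt(ad.sum_(y * y, axis=1, keepdims=True))
    nv = ad.value_of(norms)
    if np.any(nv < _NORM_FLOOR):
        raise ValidationError(
            "degenerate encoding: a pre-normalization latent vector has "
            "(near-)zero norm")
    return y * (norms ** -1.0)


def encode(xr, codec: FlavorCodec):
    """Reduced vectors -> latent rows on the unit hypersphere.

    Accepts ndarrays or autodiff Tensors (training path). Rows are L2
    normalized; a zero pre-normalization vector is an error.
    """
    single = ad.value_of(xr).ndim == 1
    if single:
        xr = ad.reshape(xr, (1, -1))
    W = codec.encoder_weight if not isinstance(codec.encoder_weight, ad.Tensor) else codec.encoder_weight
    y = ad.matmul(xr, ad.transpose(W)) + codec.encoder_bias
    z = _l2_normalize_rows(y)
    if single and not isinstance(z, ad.Tensor):
        return z[0]
    return z


def decode(z, codec: FlavorCodec):
    """Latent rows -> reduced vectors (single affine layer)."""
    single = ad.value_of(z).ndim == 1
    if single:
        z = ad.reshape(z, (1, -1))
    out = ad.matmul(z, ad.transpose(codec.decoder_weight)) + codec.decoder_bias
    if single and not isinstance(out, ad.Tensor):
        return out[0]
    return out


def predict_path(x: EdgeVectorSet, model: CodecModel, source: str,
                 target: str) -> EdgeVectorSet:
    """Translate flavor ``source`` into flavor ``target`` for every subject.

    restore_target(decode_target(encode_source(reduce_source(x)))).
    Deterministic (no dropout at inference).
    """
    src_flavor = model.flavor(source)
    tgt_flavor = model.flavor(target)
    if x.flavor.name != src_flavor.name:
        raise ValidationError(
            f"input edge set is flavor {x.flavor.name!r}, expected {source!r}")
    xr = reduce(x.data, model.reductions[source])
    z = encode(xr, model.codecs[source])
    yr = decode(z, model.codecs[target])
    y = restore(yr, model.reductions[target])
    return EdgeVectorSet(tgt_flavor, list(x.subject_ids), y)


def fusion_subset(model: CodecModel, rule: str,
                  target: str | None = None) -> list[str]:
    """Flavor names included by a fusion rule.

    Rules: ``fusion`` (all flavors), ``fusionFC``/``fusionSC`` (one
    modality), and the ``-parc`` variants which additionally exclude every
    flavor sharing the target flavor's parcellation.
    """
    rule_l = rule.lower()
    base = rule_l.replace("-parc", "")
    if base in ("fusion", "all"):
        names = [f.name for f in model.flavors]
    elif base in ("fusionfc", "fc"):
        names = [f.name for f in model.flavors if f.modality == "FC"]
    elif base in ("fusionsc", "sc"):
        names = [f.name for f in model.flavors if f.modality == "SC"]
    else:
        raise ValidationError(f"unknown fusion rule {rule!r}")
    if rule_l.endswith("-parc"):
        if target is None:
            raise ValidationError(f"fusion rule {rule!r} needs a target flavor")
        atlas = model.flavor(target).atlas
        names = [n for n in names if model.flavor(n).atlas != atlas]
    if not names:
        raise ValidationError(f"fusion rule {rule!r} selects no flavors")
    return names


def fuse(latents: list[LatentMatrix], include: list[str] | None = None,
         renormalize: bool = False, label: str = "fusion") -> LatentMatrix:
    """Average latent vectors over a subset of flavors.

    By default the plain elementwise mean is decoded (no re-normalization);
    pass ``renormalize=True`` to re-project the average onto the hypersphere.
    """
    if include is not None:
        latents = [z for z in latents if z.source in include]
    if not latents:
        raise ValidationError("fusion subset is empty")
    ids = latents[0].subject_ids
    for z in latents[1:]:
        if z.subject_ids != ids:
            raise ValidationError("latents do not share subject ordering")
    avg = np.mean([z.data for z in latents], axis=0)
    if renormalize:
        norms = np.linalg.norm(avg, axis=1, keepdims=True)
        if np.any(norms < _NORM_FLOOR):
            raise ValidationError(
                "degenerate fusion: averaged latent vector has zero norm")
        avg = avg / norms
    return LatentMatrix(list(ids), avg, source=label)


def predict_fusion(edge_sets: dict[str, EdgeVectorSet], model: CodecModel,
                   rule: str, target: str,
                   renormalize: bool = False) -> EdgeVectorSet:
    """Fusion prediction of ``target`` from a subset of input flavors."""
    names = fusion_subset(model, rule, target=target)
    latents = [model.encode_edges(edge_sets[n], n) for n in names]
    fused = fuse(latents, renormalize=renormalize, label=rule)
    yr = decode(fused.data, model.codecs[target])
    y = restore(yr, model.reductions[target])
    return EdgeVectorSet(model.flavor(target), list(fused.subject_ids), y)


def adapt_population_mean(x_new: EdgeVectorSet | np.ndarray,
                          mu_new: np.ndarray,
                          mu_train: np.ndarray):
    """Domain adaptation by population-mean shift.

    Maps a new cohort's per-flavor population mean onto the training
    population mean before encoding: x - mu_new + mu_train. A pure location
    shift; no variance matching.
    """
    mu_new = np.asarray(mu_new, dtype=float).ravel()
    mu_train = np.asarray(mu_train, dtype=float).ravel()
    if mu_new.shape != mu_train.shape:
        raise ValidationError("mean vectors have mismatched shapes")
    if isinstance(x_new, EdgeVectorSet):
        if x_new.data.shape[1] != mu_new.size:
            raise ValidationError("edge dimension does not match mean vectors")
        return EdgeVectorSet(x_new.flavor, list(x_new.subject_ids),
                             x_new.data - mu_new + mu_train)
    X = np.asarray(x_new, dtype=float)
    if X.shape[-1] != mu_new.size:
        raise ValidationError("edge dimension does not match mean vectors")
    return X - mu_new + mu_train


def latent_similarity(z: LatentMatrix | np.ndarray,
                      metric: str = "pearson") -> np.ndarray:
    """Inter-subject similarity matrix of latent rows (Pearson or cosine)."""
    X = z.data if isinstance(z, LatentMatrix) else np.asarray(z, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("latent similarity needs at least 2 subjects")
    if metric == "pearson":
        sd = X.std(axis=1)
        const = sd < _NORM_FLOOR
        if np.any(const):
            warnings.warn("constant latent rows: their Pearson similarity set to 0")
        Xc = X - X.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Xc, axis=1)
        denom[const] = 1.0
        Xn = Xc / denom[:, None]
        S = Xn @ Xn.T
        S[const, :] = 0.0
        S[:, const] = 0.0
        np.fill_diagonal(S, np.where(const, 0.0, np.diag(S)))
        return S
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = norms < _NORM_FLOOR
        if np.any(zero):
            warnings.warn("zero-norm latent rows: their cosine similarity set to 0")
        norms[zero] = 1.0
        Xn = X / norms[:, None]
        S = Xn @ Xn.T
        S[zero, :] = 0.0
        S[:, zero] = 0.0
        return S
    raise ValidationError(f"unknown similarity metric {metric!r}")


# ---------------------------------------------------------------------------
# checkpoint I/O (HDF5 container: one group per flavor + registry)


def write_model_group(h, model: CodecModel) -> None:
    """Write a model into an open HDF5 file or group."""
    h.attrs["format_version"] = CHECKPOINT_FORMAT_VERSION
    h.attrs["latent_dim"] = model.latent_dim
    h.attrs["flavor_names"] = [f.name for f in model.flavors]
    for fl in model.flavors:
        g = h.create_group(f"flavors/{fl.name}")
        g.attrs.update({
            "modality": fl.modality, "atlas": fl.atlas,
            "n_regions": fl.n_regions,
            "fc_variant": fl.fc_variant or "",
            "sc_variant": fl.sc_variant or "",
        })
        r = model.reductions[fl.name]
        g.create_dataset("train_mean", data=r.train_mean)
        g.create_dataset("components", data=r.components)
        g.create_dataset("component_scale", data=r.component_scale)
        g.attrs["whiten"] = bool(r.whiten)
        c = model.codecs[fl.name]
        g.create_dataset("encoder_weight", data=c.encoder_weight)
        g.create_dataset("encoder_bias", data=c.encoder_bias)
        g.create_dataset("decoder_weight", data=c.decoder_weight)
        g.create_dataset("decoder_bias", data=c.decoder_bias)


def read_model_group(h) -> CodecModel:
    """Read a model from an open HDF5 file or group."""
    names = [n if isinstance(n, str) else n.decode()
             for n in h.attrs["flavor_names"]]
    latent_dim = int(h.attrs["latent_dim"])
    flavors, reductions, codecs = [], {}, {}
    for name in names:
        g = h[f"flavors/{name}"]
        fl = FlavorSpec(
            name=name, modality=str(g.attrs["modality"]),
            atlas=str(g.attrs["atlas"]), n_regions=int(g.attrs["n_regions"]),
            fc_variant=str(g.attrs["fc_variant"]) or None,
            sc_variant=str(g.attrs["sc_variant"]) or None,
        )
        flavors.append(fl)
        reductions[name] = ReductionModel(
            fl, g["train_mean"][:], g["components"][:],
            g["component_scale"][:], whiten=bool(g.attrs["whiten"]))
        codecs[name] = FlavorCodec(
            fl, g["encoder_weight"][:], g["encoder_bias"][:],
            g["decoder_weight"][:], g["decoder_bias"][:])
    return CodecModel(flavors, reductions, codecs, latent_dim=latent_dim)


def save_model(path, model: CodecModel) -> None:
    with h5py.File(path, "w") as h:
        write_model_group(h, model)


def load_model(path) -> CodecModel:
    with h5py.File(path, "r") as h:
        return read_model_group(h)

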