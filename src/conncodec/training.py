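"""Two-stage training of the codec model.

Each epoch has two stages:

1. **Path-wise** — for every ordered flavor pair (i, j), in an order
   reshuffled each epoch, batches of subjects are pushed through
   Encoder_i -> Decoder_j; the reconstruction loss (against flavor j's
   reduced data) plus the latent dispersion loss (on z_i) is backpropagated,
   updating only Encoder_i and Decoder_j.
2. **Latent consistency** — z_i is recomputed for every flavor on the full
   training cohort and the cross-flavor consistency loss is backpropagated
   through all encoders.

Optimization is AdamW (decoupled weight decay); dropout can be applied to
encoder and decoder inputs during the path-wise stage. Training is bitwise
reproducible under a fixed seed: every random draw of epoch *e* comes from a
generator keyed by (seed, e), so resuming from a checkpoint continues the
exact uninterrupted trajectory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import autodiff as ad
from .flavors import EdgeVectorSet, FlavorSpec, ValidationError, enumerate_paths
from .losses import (LossWeights, loss_latent_consistency,
                     loss_latent_dispersion, loss_recon)
from .model import (CodecModel, FlavorCodec, LatentMatrix, decode, encode,
                    init_codec, read_model_group, write_model_group)
from .reduction import fit_reduction, reduce, restore
from .metrics import avgcorr_demean, avgrank

__all__ = ["TrainConfig", "TrainState", "AdamW", "fit_model", "train",
           "pathwise_stage", "consistency_stage", "validate_epoch",
           "extend_new_flavor", "desk_train_config",
           "save_checkpoint", "load_checkpoint"]

_CODEC_ATTRS = ("encoder_weight", "encoder_bias", "decoder_weight", "decoder_bias")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults mirror the full-scale reference schedule (AdamW lr 1e-4,
    weight decay 1e-2, dropout 0.5, batches of 41 subjects); see
    :func:`desk_train_config` for the scaled-down schedule used on small
    synthetic cohorts.
    """

    n_epochs: int = 100
    n_batch: int = 41
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    dropout_rate: float = 0.5
    seed: int = 0
    checkpoint_every: int = 0     # 0 = no periodic checkpoints
    checkpoint_dir: str | None = None
    validation: bool = True

    def __post_init__(self):
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.n_batch < 2:
            raise ValidationError("n_batch must be >= 2 (contrastive terms "
                                  "need at least 2 subjects)")


def desk_train_config(n_epochs: int = 200, seed: int = 0, **kw) -> TrainConfig:
    """Scaled-down schedule for desk-scale synthetic cohorts.

    At a few hundred subjects and tens of reduced dimensions the model is
    small enough that the full-scale regularization (dropout 0.5) mostly
    injects noise; the desk schedule uses a higher learning rate, light
    weight decay and no dropout so 200 epochs suffice.
    """
    defaults = dict(n_epochs=n_epochs, learning_rate=1e-3, weight_decay=1e-3,
                    dropout_rate=0.0, seed=seed)
    defaults.update(kw)
    return TrainConfig(**defaults)


@dataclass
class TrainState:
    """Per-epoch loss traces, validation metrics and bookkeeping."""

    epoch: int = 0
    loss_traces: list = field(default_factory=list)   # one dict per epoch
    val_traces: list = field(default_factory=list)    # one dict per epoch (or None)
    selected_epoch: int | None = None

    def summary(self) -> str:
        lines = []
        for e, (lt, vt) in enumerate(zip(self.loss_traces, self.val_traces)):
            terms = " ".join(f"{k}={v:.4g}" for k, v in sorted(lt.items()))
            if vt:
                terms += (f" val_avgrank={vt['avgrank']:.3f}"
                          f" val_avgcorr_demean={vt['avgcorr_demean']:.3f}")
            lines.append(f"epoch {e}: {terms}")
        return "\n".join(lines)


class AdamW:
    """AdamW over a dict of named parameter Tensors (decoupled weight decay)."""

    def __init__(self, params: dict[str, ad.Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.state = {name: {"m": np.zeros_like(p.value),
                             "v": np.zeros_like(p.value), "t": 0}
                      for name, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self, names=None):
        """Apply one update to the named parameters (all if None)."""
        b1, b2 = self.betas
        for name in (names if names is not None else self.params):
            p = self.params[name]
            if p.grad is None:
                continue
            st = self.state[name]
            st["t"] += 1
            st["m"] = b1 * st["m"] + (1 - b1) * p.grad
            st["v"] = b2 * st["v"] + (1 - b2) * p.grad * p.grad
            mhat = st["m"] / (1 - b1 ** st["t"])
            vhat = st["v"] / (1 - b2 ** st["t"])
            p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_arrays(self):
        return self.state


def _codec_param_tensors(model: CodecModel,
                         flavors: list[str] | None = None) -> dict[str, ad.Tensor]:
    """Wrap codec arrays as gradient-tracking Tensors sharing memory."""
    params: dict[str, ad.Tensor] = {}
    for name in (flavors if flavors is not None else list(model.codecs)):
        codec = model.codecs[name]
        for attr in _CODEC_ATTRS:
            arr = np.ascontiguousarray(getattr(codec, attr), dtype=np.float64)
            t = ad.Tensor(arr, requires_grad=True)
            setattr(codec, attr, t.value)   # share storage: opt updates codec
            params[f"{name}.{attr}"] = t
    return params


class _TensorCodec:
    """Codec view whose fields are the parameter Tensors (training forward)."""

    def __init__(self, params: dict[str, ad.Tensor], name: str):
        for attr in _CODEC_ATTRS:
            setattr(self, attr, params[f"{name}.{attr}"])


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    return (rng.random(shape) >= rate) / (1.0 - rate)


def fit_model(flavors: list[FlavorSpec], train_edges: dict[str, EdgeVectorSet],
              n_comp: int = 256, latent_dim: int = 128,
              seed: int = 0, whiten: bool = True) -> CodecModel:
    """Fit per-flavor reductions on training data and initialize codecs."""
    rng = np.random.default_rng(seed)
    reductions, codecs = {}, {}
    for fl in flavors:
        r = fit_reduction(train_edges[fl.name], n_comp=n_comp, whiten=whiten)
        reductions[fl.name] = r
        codecs[fl.name] = init_codec(fl, r.n_comp, latent_dim, rng)
    return CodecModel(flavors, reductions, codecs, latent_dim=latent_dim,
                      config={"n_comp": n_comp, "seed": seed})


def _check_nan(value: float, path: tuple[str, str], term: str):
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite loss ({term}) on path {path[0]} -> {path[1]}; "
            "aborting training")


def pathwise_stage(model: CodecModel, params: dict[str, ad.Tensor],
                   reduced_train: dict[str, np.ndarray], config: TrainConfig,
                   weights: LossWeights, opt: AdamW,
                   rng: np.random.Generator) -> dict[str, float]:
    """Stage 1 of an epoch: per-path reconstruction + dispersion updates."""
    names = [f.name for f in model.flavors]
    paths = [(p["source"], p["target"]) for p in enumerate_paths(names)]
    rng.shuffle(paths)
    n_train = next(iter(reduced_train.values())).shape[0]
    if n_train < config.n_batch:
        warnings.warn(f"n_train={n_train} < n_batch={config.n_batch}: "
                      "using a single smaller batch")
    sums: dict[str, float] = {}
    count = 0
    for src, tgt in paths:
        perm = rng.permutation(n_train)
        enc = _TensorCodec(params, src)
        dec = _TensorCodec(params, tgt)
        for start in range(0, n_train, config.n_batch):
            idx = perm[start:start + config.n_batch]
            if idx.size < 2:
                continue
            x_in = reduced_train[src][idx]
            x_true = reduced_train[tgt][idx]
            if config.dropout_rate > 0:
                x_in = x_in * _dropout_mask(rng, x_in.shape, config.dropout_rate)
            z = encode(x_in, enc)
            z_dec = z
            if config.dropout_rate > 0:
                z_dec = z * _dropout_mask(rng, z.shape, config.dropout_rate)
            pred = decode(z_dec, dec)
            l_rec, bd_rec = loss_recon(x_true, pred, weights)
            l_disp, bd_disp = loss_latent_dispersion(z, weights)
            total = l_rec + l_disp
            for term, v in {**bd_rec, **bd_disp}.items():
                _check_nan(v, (src, tgt), term)
            opt.zero_grad()
            total.backward()
            opt.step([f"{src}.encoder_weight", f"{src}.encoder_bias",
                      f"{tgt}.decoder_weight", f"{tgt}.decoder_bias"])
            for term, v in {**bd_rec, **bd_disp, "total": float(total.value)}.items():
                sums[term] = sums.get(term, 0.0) + v
            count += 1
    return {k: v / max(count, 1) for k, v in sums.items()}


def consistency_stage(model: CodecModel, params: dict[str, ad.Tensor],
                      reduced_train: dict[str, np.ndarray],
                      config: TrainConfig, weights: LossWeights,
                      opt: AdamW) -> dict[str, float]:
    """Stage 2 of an epoch: full-cohort cross-flavor latent consistency."""
    names = [f.name for f in model.flavors]
    if len(names) < 2:
        warnings.warn("single flavor: latent consistency stage skipped")
        return {}
    zs = {}
    for name in names:
        enc = _TensorCodec(params, name)
        zs[name] = encode(reduced_train[name], enc)
    total, bd = loss_latent_consistency(zs, weights)
    _check_nan(float(total.value), ("all", "all"), "z.sim")
    opt.zero_grad()
    total.backward()
    opt.step([f"{n}.encoder_weight" for n in names]
             + [f"{n}.encoder_bias" for n in names])
    return bd


def validate_epoch(model: CodecModel, val_edges: dict[str, EdgeVectorSet]) -> dict:
    """Per-path avgrank and demeaned correlation on restored predictions.

    Predictions are mapped back to native edge dimensions before scoring;
    the demeaning mean is each target flavor's training mean (stored in its
    reduction).
    """
    names = [f.name for f in model.flavors]
    per_path = {}
    for src in names:
        xr = reduce(val_edges[src].data, model.reductions[src])
        z = encode(xr, model.codecs[src])
        for tgt in names:
            pred = restore(decode(z, model.codecs[tgt]), model.reductions[tgt])
            meas = val_edges[tgt].data
            mu = model.reductions[tgt].train_mean
            per_path[(src, tgt)] = {
                "avgrank": avgrank(meas, pred),
                "avgcorr_demean": avgcorr_demean(meas, pred, mu),
            }
    mean_rank = float(np.mean([v["avgrank"] for v in per_path.values()]))
    mean_acd = float(np.mean([v["avgcorr_demean"] for v in per_path.values()]))
    return {"avgrank": mean_rank, "avgcorr_demean": mean_acd,
            "per_path": per_path}


def _reduced_training_data(model: CodecModel,
                           train_edges: dict[str, EdgeVectorSet]) -> dict[str, np.ndarray]:
    names = [f.name for f in model.flavors]
    ids = train_edges[names[0]].subject_ids
    for n in names[1:]:
        if train_edges[n].subject_ids != ids:
            raise ValidationError(f"flavor {n} training subjects are misaligned")
    return {n: reduce(train_edges[n].data, model.reductions[n]) for n in names}


def train(model: CodecModel, train_edges: dict[str, EdgeVectorSet],
          val_edges: dict[str, EdgeVectorSet] | None, config: TrainConfig,
          weights: LossWeights | None = None,
          resume_from: str | None = None) -> TrainState:
    """Run the two-stage training loop; mutates ``model`` in place.

    With ``checkpoint_every > 0`` and a ``checkpoint_dir``, periodic
    checkpoints (model + optimizer state + traces) are written; pass one as
    ``resume_from`` to continue an interrupted run — the continuation is
    bitwise identical to the uninterrupted one under the same config.
    """
    weights = weights or LossWeights()
    params = _codec_param_tensors(model)
    opt = AdamW(params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    state = TrainState()
    start_epoch = 0
    if resume_from is not None:
        start_epoch = _load_into(resume_from, model, params, opt, state)
    reduced = _reduced_training_data(model, train_edges)
    for epoch in range(start_epoch, config.n_epochs):
        rng = np.random.default_rng([config.seed % (2**31), epoch])
        losses = pathwise_stage(model, params, reduced, config, weights, opt, rng)
        losses.update(consistency_stage(model, params, reduced, config,
                                        weights, opt))
        state.loss_traces.append(losses)
        if config.validation and val_edges is not None:
            vt = validate_epoch(model, val_edges)
            state.val_traces.append({"avgrank": vt["avgrank"],
                                     "avgcorr_demean": vt["avgcorr_demean"]})
        else:
            state.val_traces.append(None)
        state.epoch = epoch + 1
        if (config.checkpoint_every and config.checkpoint_dir
                and (epoch + 1) % config.checkpoint_every == 0):
            path = f"{config.checkpoint_dir}/checkpoint_epoch{epoch + 1:05d}.h5"
            save_checkpoint(path, model, opt, state)
    scored = [i for i, v in enumerate(state.val_traces) if v is not None]
    if scored:
        state.selected_epoch = max(
            scored, key=lambda i: state.val_traces[i]["avgrank"]
            + state.val_traces[i]["avgcorr_demean"])
    return state


def extend_new_flavor(model: CodecModel, new_train: EdgeVectorSet,
                      fusion_latents: LatentMatrix, config: TrainConfig,
                      weights: LossWeights | None = None,
                      n_comp: int | None = None) -> tuple[FlavorCodec, "object"]:
    """Train one new flavor codec against a frozen base model.

    The new encoder/decoder is trained as an autoencoder with an extra
    alignment term pulling its latents toward the precomputed fusion latents
    of the same training subjects (weight ``w_zs``). The base model is not
    touched.

    Returns ``(codec, reduction)`` for the new flavor.
    """
    weights = weights or LossWeights()
    if list(new_train.subject_ids) != list(fusion_latents.subject_ids):
        raise ValidationError("new-flavor training subjects do not match the "
                              "fusion latents")
    if n_comp is None:
        n_comp = int(model.config.get("n_comp", 256))
    red = fit_reduction(new_train, n_comp=n_comp)
    xr_all = reduce(new_train.data, red)
    rng0 = np.random.default_rng([config.seed % (2**31), 999_983])
    codec = init_codec(new_train.flavor, red.n_comp, model.latent_dim, rng0)
    tmp_model = CodecModel([new_train.flavor], {new_train.flavor.name: red},
                           {new_train.flavor.name: codec},
                           latent_dim=model.latent_dim)
    params = _codec_param_tensors(tmp_model)
    opt = AdamW(params, lr=config.learning_rate,
                weight_decay=config.weight_decay)
    name = new_train.flavor.name
    zf = fusion_latents.data
    n_train = xr_all.shape[0]
    for epoch in range(config.n_epochs):
        rng = np.random.default_rng([config.seed % (2**31), epoch, 1])
        perm = rng.permutation(n_train)
        enc = _TensorCodec(params, name)
        dec = _TensorCodec(params, name)
        for start in range(0, n_train, config.n_batch):
            idx = perm[start:start + config.n_batch]
            if idx.size < 2:
                continue
            x_in = xr_all[idx]
            if config.dropout_rate > 0:
                x_in = x_in * _dropout_mask(rng, x_in.shape, config.dropout_rate)
            z = encode(x_in, enc)
            pred = decode(z, dec)
            l_rec, _ = loss_recon(xr_all[idx], pred, weights)
            l_disp, _ = loss_latent_dispersion(z, weights)
            dz = z - zf[idx]
            l_align = weights.w_zs * (ad.mean(dz * dz))
            total = l_rec + l_disp + l_align
            _check_nan(float(total.value), (name, name), "total")
            opt.zero_grad()
            total.backward()
            opt.step()
    return codec, red


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path, model: CodecModel, opt: AdamW, state: TrainState) -> None:
    with h5py.File(path, "w") as h:
        mg = h.create_group("model")
        write_model_group(mg, model)
        og = h.create_group("optimizer")
        for name, st in opt.state.items():
            g = og.create_group(name)
            g.create_dataset("m", data=st["m"])
            g.create_dataset("v", data=st["v"])
            g.attrs["t"] = st["t"]
        sg = h.create_group("state")
        sg.attrs["epoch"] = state.epoch
        sg.attrs["loss_traces"] = json.dumps(state.loss_traces)
        sg.attrs["val_traces"] = json.dumps(state.val_traces)


def load_checkpoint(path) -> tuple[CodecModel, dict, TrainState]:
    """Load a checkpoint into fresh objects (model, optimizer state, state)."""
    with h5py.File(path, "r") as h:
        model = read_model_group(h["model"])
        opt_state = {}
        for name, g in h["optimizer"].items():
            opt_state[name] = {"m": g["m"][:], "v": g["v"][:],
                               "t": int(g.attrs["t"])}
        sg = h["state"]
        state = TrainState(epoch=int(sg.attrs["epoch"]),
                           loss_traces=json.loads(sg.attrs["loss_traces"]),
                           val_traces=json.loads(sg.attrs["val_traces"]))
    return model, opt_state, state


def _load_into(path, model: CodecModel, params: dict[str, ad.Tensor],
               opt: AdamW, state: TrainState) -> int:
    """Restore checkpointed weights/optimizer/traces into live objects."""
    ck_model, opt_state, ck_state = load_checkpoint(path)
    for name, codec in model.codecs.items():
        src = ck_model.codecs[name]
        for attr in _CODEC_ATTRS:
            getattr(codec, attr)[...] = getattr(src, attr)
    for name, st in opt_state.items():
        opt.state[name]["m"][...] = st["m"]
        opt.state[name]["v"][...] = st["v"]
        opt.state[name]["t"] = st["t"]
    state.epoch = ck_state.epoch
    state.loss_traces = list(ck_state.loss_traces)
    state.val_traces = list(ck_state.val_traces)
    return ck_state.epoch
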