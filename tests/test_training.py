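
import numpy as np
import pytest

from conncodec.flavors import EdgeVectorSet, FlavorSpec
from conncodec.losses import LossWeights
from conncodec.model import LatentMatrix, encode, fuse, predict_path
from conncodec.training import (AdamW, TrainConfig, consistency_stage,
                                desk_train_config, extend_new_flavor,
                                fit_model, load_checkpoint, save_checkpoint,
                                train, validate_epoch,
                                _codec_param_tensors)
from conncodec import autodiff as ad

from conftest import random_edge_set


def two_flavor_problem(seed=0, n=60, shared_rank=3):
    """Two flavors that are different affine views of a shared low-rank latent."""
    rng = np.random.default_rng(seed)
    fa = FlavorSpec("P6_FC", "FC", "P6", 6, fc_variant="pearson")     # 15 edges
    fb = FlavorSpec("Q7_FC", "FC", "Q7", 7, fc_variant="pearson")     # 21 edges
    U = rng.standard_normal((n, shared_rank))
    Wa = rng.standard_normal((shared_rank, 15))
    Wb = rng.standard_normal((shared_rank, 21))
    ids = [f"s{i:03d}" for i in range(n)]
    ea = EdgeVectorSet(fa, ids, U @ Wa + 0.05 * rng.standard_normal((n, 15)))
    eb = EdgeVectorSet(fb, ids, U @ Wb + 0.05 * rng.standard_normal((n, 21)))
    return [fa, fb], {fa.name: ea, fb.name: eb}


def codec_snapshot(model):
    return {name: {a: getattr(c, a).copy()
                   for a in ("encoder_weight", "encoder_bias",
                             "decoder_weight", "decoder_bias")}
            for name, c in model.codecs.items()}


def snapshots_equal(a, b):
    return all(np.array_equal(a[n][k], b[n][k]) for n in a for k in a[n])


class TestAdamW:
    def test_single_step_matches_update_formula(self):
        p = ad.Tensor(np.array([1.0, -2.0]), requires_grad=True)
        g = np.array([0.5, -0.25])
        p.grad = g.copy()
        opt = AdamW({"p": p}, lr=0.01, weight_decay=0.1)
        x0 = p.value.copy()
        opt.step()
        # hand-applied AdamW step 1: mhat = g, vhat = g^2
        expected = x0 - 0.01 * 0.1 * x0 - 0.01 * g / (np.abs(g) + 1e-8)
        assert np.allclose(p.value, expected, atol=1e-12)

    def test_no_grad_no_update(self):
        p = ad.Tensor(np.ones(3), requires_grad=True)
        opt = AdamW({"p": p}, lr=0.1)
        opt.step()
        assert np.array_equal(p.value, np.ones(3))


class TestTrainLoop:
    def test_zero_learning_rate_leaves_model_unchanged(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        before = codec_snapshot(model)
        cfg = TrainConfig(n_epochs=2, learning_rate=0.0, weight_decay=0.0,
                          dropout_rate=0.0, n_batch=16, seed=0,
                          validation=False)
        train(model, edges, None, cfg)
        assert snapshots_equal(before, codec_snapshot(model))

    def test_fixed_seed_reproduces_loss_trace_bitwise(self):
        flavors, edges = two_flavor_problem()
        traces = []
        for _ in range(2):
            model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
            cfg = desk_train_config(n_epochs=4, seed=7, n_batch=16,
                                    validation=False)
            st = train(model, edges, None, cfg)
            traces.append(st.loss_traces)
        assert traces[0] == traces[1]

    def test_training_loss_decreases_on_toy_problem(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        cfg = desk_train_config(n_epochs=40, seed=0, n_batch=16,
                                validation=False)
        st = train(model, edges, None, cfg)
        # strictly decreasing over epoch-averaged windows (the floor is set
        # by whitened noise components the latent cannot encode)
        totals = np.array([t["total"] for t in st.loss_traces])
        windows = totals.reshape(4, 10).mean(axis=1)
        assert np.all(np.diff(windows) < 0)

    def test_zero_epochs_returns_initial_model(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        before = codec_snapshot(model)
        st = train(model, edges, None,
                   TrainConfig(n_epochs=0, validation=False))
        assert st.loss_traces == [] and st.epoch == 0
        assert snapshots_equal(before, codec_snapshot(model))

    def test_small_cohort_single_batch_warning(self):
        flavors, edges = two_flavor_problem(n=10)
        model = fit_model(flavors, edges, n_comp=6, latent_dim=4, seed=1)
        cfg = desk_train_config(n_epochs=1, seed=0, n_batch=41,
                                validation=False)
        with pytest.warns(UserWarning, match="single smaller batch"):
            train(model, edges, None, cfg)

    def test_inference_deterministic_after_dropout_training(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        cfg = TrainConfig(n_epochs=2, learning_rate=1e-3, dropout_rate=0.5,
                          n_batch=16, seed=0, validation=False)
        train(model, edges, None, cfg)
        a = predict_path(edges["P6_FC"], model, "P6_FC", "Q7_FC").data
        b = predict_path(edges["P6_FC"], model, "P6_FC", "Q7_FC").data
        assert np.array_equal(a, b)


class TestConsistencyStage:
    def test_reduces_interflavor_latent_mse(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        from conncodec.reduction import reduce
        reduced = {f.name: reduce(edges[f.name].data, model.reductions[f.name])
                   for f in flavors}

        def inter_mse():
            za = encode(reduced["P6_FC"], model.codecs["P6_FC"])
            zb = encode(reduced["Q7_FC"], model.codecs["Q7_FC"])
            return np.mean((za - zb) ** 2)

        before = inter_mse()
        params = _codec_param_tensors(model)
        cfg = TrainConfig(n_epochs=1, learning_rate=1e-3, dropout_rate=0.0,
                          n_batch=16, validation=False)
        opt = AdamW(params, lr=cfg.learning_rate, weight_decay=0.0)
        for _ in range(20):
            consistency_stage(model, params, reduced, cfg, LossWeights(), opt)
        assert inter_mse() < before

    def test_identical_latents_zero_gradient(self):
        # one flavor duplicated under two names -> same codec init + data
        rng = np.random.default_rng(0)
        fa = FlavorSpec("A5_FC", "FC", "A5", 5, fc_variant="pearson")
        fb = FlavorSpec("B5_FC", "FC", "B5", 5, fc_variant="pearson")
        data = rng.standard_normal((20, 10))
        ids = [f"s{i}" for i in range(20)]
        edges = {fa.name: EdgeVectorSet(fa, ids, data),
                 fb.name: EdgeVectorSet(fb, ids, data.copy())}
        model = fit_model([fa, fb], edges, n_comp=6, latent_dim=4, seed=2)
        # force identical codecs
        for attr in ("encoder_weight", "encoder_bias", "decoder_weight",
                     "decoder_bias"):
            setattr(model.codecs[fb.name], attr,
                    getattr(model.codecs[fa.name], attr).copy())
        from conncodec.reduction import reduce
        reduced = {n: reduce(edges[n].data, model.reductions[n]) for n in edges}
        params = _codec_param_tensors(model)
        before = codec_snapshot(model)
        cfg = TrainConfig(n_epochs=1, learning_rate=1e-2, dropout_rate=0.0,
                          validation=False)
        opt = AdamW(params, lr=cfg.learning_rate, weight_decay=0.0)
        consistency_stage(model, params, reduced, cfg, LossWeights(), opt)
        assert snapshots_equal(before, codec_snapshot(model))


class TestValidation:
    def test_untrained_model_near_chance_on_exchangeable_subjects(self, rng):
        fa = FlavorSpec("R8_FC", "FC", "R8", 8, fc_variant="pearson")
        edges = {fa.name: random_edge_set(fa, 40, rng)}
        model = fit_model([fa], edges, n_comp=8, latent_dim=4, seed=3)
        val = {fa.name: random_edge_set(fa, 30, rng)}
        out = validate_epoch(model, val)
        assert 0.25 < out["avgrank"] < 0.75

    def test_perfect_toy_model_avgrank_one(self):
        # rank-limited data + closed-form-learnable: train until ~perfect
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        cfg = desk_train_config(n_epochs=200, seed=0, n_batch=16,
                                validation=False)
        train(model, edges, None, cfg)
        out = validate_epoch(model, edges)
        assert out["avgrank"] > 0.99

    def test_validation_matches_metrics_module(self):
        from conncodec.metrics import avgcorr_demean, avgrank
        from conncodec.reduction import reduce, restore
        from conncodec.model import decode
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        out = validate_epoch(model, edges)
        src, tgt = "P6_FC", "Q7_FC"
        xr = reduce(edges[src].data, model.reductions[src])
        pred = restore(decode(encode(xr, model.codecs[src]),
                              model.codecs[tgt]), model.reductions[tgt])
        assert out["per_path"][(src, tgt)]["avgrank"] == pytest.approx(
            avgrank(edges[tgt].data, pred))
        assert out["per_path"][(src, tgt)]["avgcorr_demean"] == pytest.approx(
            avgcorr_demean(edges[tgt].data, pred,
                           model.reductions[tgt].train_mean))


class TestCheckpointResume:
    def test_resume_matches_uninterrupted_run_bitwise(self, tmp_path):
        flavors, edges = two_flavor_problem()
        cfg_kw = dict(n_epochs=6, seed=11, n_batch=16, validation=False)

        model_a = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        st_a = train(model_a, edges, None, desk_train_config(**cfg_kw))

        model_b = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        cfg_b = desk_train_config(**{**cfg_kw, "n_epochs": 3})
        cfg_b.checkpoint_every = 3
        cfg_b.checkpoint_dir = str(tmp_path)
        train(model_b, edges, None, cfg_b)
        ck = tmp_path / "checkpoint_epoch00003.h5"
        assert ck.exists()

        model_c = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        st_c = train(model_c, edges, None, desk_train_config(**cfg_kw),
                     resume_from=str(ck))
        assert st_c.loss_traces == st_a.loss_traces
        assert snapshots_equal(codec_snapshot(model_a), codec_snapshot(model_c))

    def test_checkpoint_roundtrip(self, tmp_path):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        params = _codec_param_tensors(model)
        opt = AdamW(params, lr=1e-3)
        from conncodec.training import TrainState
        st = TrainState(epoch=2, loss_traces=[{"total": 1.0}, {"total": 0.5}],
                        val_traces=[None, None])
        save_checkpoint(tmp_path / "ck.h5", model, opt, st)
        m2, opt_state, st2 = load_checkpoint(tmp_path / "ck.h5")
        assert st2.epoch == 2 and st2.loss_traces == st.loss_traces
        assert np.array_equal(m2.codecs["P6_FC"].encoder_weight,
                              model.codecs["P6_FC"].encoder_weight)


class TestExtendNewFlavor:
    @pytest.fixture(scope="module")
    def base(self):
        flavors, edges = two_flavor_problem()
        model = fit_model(flavors, edges, n_comp=8, latent_dim=4, seed=1)
        cfg = desk_train_config(n_epochs=200, seed=0, n_batch=16,
                                validation=False)
        train(model, edges, None, cfg)
        latents = [model.encode_edges(edges[n], n) for n in edges]
        fused = fuse(latents, label="fusion")
        return model, edges, fused

    def test_new_latents_align_to_fusion(self, base):
        model, edges, fused = base
        # "new" flavor = copy of an existing flavor's data under a new name
        fl = FlavorSpec("N6_FC", "FC", "N6", 6, fc_variant="pearson")
        new = EdgeVectorSet(fl, list(edges["P6_FC"].subject_ids),
                            edges["P6_FC"].data.copy())
        cfg = desk_train_config(n_epochs=300, seed=2, n_batch=16,
                                validation=False)
        codec, red = extend_new_flavor(model, new, fused, cfg)
        from conncodec.reduction import reduce
        z_new = encode(reduce(new.data, red), codec)
        # each subject's new latent should rank own fusion latent above
        # (almost) every other subject's
        sims = z_new @ (fused.data / np.linalg.norm(fused.data, axis=1,
                                                    keepdims=True)).T
        own = np.diag(sims)
        rank = np.mean([np.mean(np.delete(sims[i], i) < own[i])
                        for i in range(len(own))])
        assert own.mean() > 0.9
        assert rank > 0.95

    def test_alignment_weight_zero_gives_unaligned_autoencoder(self, base):
        model, edges, fused = base
        fl = FlavorSpec("N6_FC", "FC", "N6", 6, fc_variant="pearson")
        new = EdgeVectorSet(fl, list(edges["P6_FC"].subject_ids),
                            edges["P6_FC"].data.copy())
        cfg = desk_train_config(n_epochs=30, seed=2, n_batch=16,
                                validation=False)
        w0 = LossWeights(w_zs=0.0)
        codec, red = extend_new_flavor(model, new, fused, cfg, weights=w0)
        from conncodec.reduction import reduce
        z_new = encode(reduce(new.data, red), codec)
        fz = fused.data / np.linalg.norm(fused.data, axis=1, keepdims=True)
        own = np.sum(z_new * fz, axis=1)
        # fusion similarity at chance: own-latent cosine not systematically high
        assert np.mean(own) < 0.5

    def test_base_model_frozen(self, base):
        model, edges, fused = base
        before = codec_snapshot(model)
        fl = FlavorSpec("N6_FC", "FC", "N6", 6, fc_variant="pearson")
        new = EdgeVectorSet(fl, list(edges["P6_FC"].subject_ids),
                            edges["P6_FC"].data.copy())
        extend_new_flavor(model, new, fused,
                          desk_train_config(n_epochs=3, seed=2, n_batch=16))
        assert snapshots_equal(before, codec_snapshot(model))

    def test_subject_mismatch_rejected(self, base):
        model, edges, fused = base
        fl = FlavorSpec("N6_FC", "FC", "N6", 6, fc_variant="pearson")
        new = EdgeVectorSet(fl, list(reversed(edges["P6_FC"].subject_ids)),
                            edges["P6_FC"].data.copy())
        from conncodec.flavors import ValidationError
        with pytest.raises(ValidationError):
            extend_new_flavor(model, new, fused,
                              desk_train_config(n_epochs=1, n_batch=16))


def test_train_config_validation():
    from conncodec.flavors import ValidationError
    with pytest.raises(ValidationError):
        TrainConfig(dropout_rate=1.0)
    with pytest.raises(ValidationError):
        TrainConfig(n_batch=1)
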