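"""InteractionLSTM: contracts, equivariance, oracles, parameter accounting."""

import math

import numpy as np
import pytest

from physvoe import autodiff as ad
from physvoe.dynamics import (DynamicsConfig, InteractionLSTM, ObjectBuffer,
                              count_parameters, dynamics_loss,
                              make_flat_variant, train_dynamics)

SMALL = DynamicsConfig(variant="plato", K=3, D=4, H=16, proj_dim=12,
                       mlp_width=8, mlp_layers=2, cam_embed=5, T=6)


@pytest.fixture()
def model():
    return InteractionLSTM(SMALL, seed=3)


def _rand_inputs(rng, cfg, B=2):
    codes = rng.normal(0, 1, (B, cfg.T, cfg.K, cfg.D)).astype(np.float32)
    cams = rng.normal(0, 1, (B, cfg.T, 7)).astype(np.float32)
    return codes, cams


# --------------------------------------------------------------------------
# independent numpy oracles
# --------------------------------------------------------------------------

def _gelu(x):
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x ** 3)))


def _mlp_np(params, name, x, layers):
    for i in range(layers):
        x = _gelu(x @ params[f"{name}_w{i}"].data + params[f"{name}_b{i}"].data)
    return x


def interaction_oracle(model, cells, buf_proj, cam):
    """Brute-force enumeration of all (from, to) message pairs."""
    cfg = model.config
    p = model.params
    B, K, H = cells.shape
    cam_e = cam @ p["cam_w"].data + p["cam_b"].data
    out = np.zeros((B, K, 2 * cfg.mlp_width), dtype=np.float64)
    for b in range(B):
        for k in range(K):
            msgs = []
            for j in range(K):          # messages to every cell, self included
                x = np.concatenate([cells[b, k], cells[b, j], cam_e[b]])
                msgs.append(_mlp_np(p, "rho", x, cfg.mlp_layers))
            for j in range(K):          # messages to every projected buffer
                x = np.concatenate([cells[b, k], buf_proj[b, j], cam_e[b]])
                msgs.append(_mlp_np(p, "lam", x, cfg.mlp_layers))
            msgs = np.stack(msgs)
            out[b, k] = np.concatenate([msgs.sum(axis=0), msgs.max(axis=0)])
    return out


class TestInteraction:
    def test_matches_bruteforce_pair_enumeration(self, model):
        rng = np.random.default_rng(0)
        B, K = 2, SMALL.K
        cells = rng.normal(0, 1, (B, K, SMALL.H)).astype(np.float32)
        buf = rng.normal(0, 1, (B, K, SMALL.proj_dim)).astype(np.float32)
        cam = rng.normal(0, 1, (B, 7)).astype(np.float32)
        got = model.interaction(ad.constant(cells), ad.constant(buf), cam).data
        want = interaction_oracle(model, cells, buf, cam)
        assert np.allclose(got, want, atol=1e-4)

    def test_invariant_to_to_set_order(self, model):
        """Sum and max aggregation make int_k independent of 'to' ordering."""
        rng = np.random.default_rng(1)
        cells = rng.normal(0, 1, (1, 3, SMALL.H)).astype(np.float32)
        buf = rng.normal(0, 1, (1, 3, SMALL.proj_dim)).astype(np.float32)
        cam = rng.normal(0, 1, (1, 7)).astype(np.float32)
        base = model.interaction(ad.constant(cells), ad.constant(buf), cam).data
        perm = [2, 0, 1]
        swapped = model.interaction(ad.constant(cells),
                                    ad.constant(buf[:, perm]), cam).data
        # permuting buffer entries (a pure 'to' set) leaves every int_k fixed
        assert np.allclose(base, swapped, atol=1e-6)

    def test_single_slot_reduces_to_self_messages(self):
        cfg = DynamicsConfig(**{**SMALL.__dict__, "K": 1})
        m = InteractionLSTM(cfg, seed=0)
        rng = np.random.default_rng(2)
        cells = rng.normal(0, 1, (1, 1, cfg.H)).astype(np.float32)
        buf = np.zeros((1, 1, cfg.proj_dim), dtype=np.float32)
        cam = rng.normal(0, 1, (1, 7)).astype(np.float32)
        got = m.interaction(ad.constant(cells), ad.constant(buf), cam).data
        want = interaction_oracle(m, cells, buf, cam)
        assert np.allclose(got, want, atol=1e-5)
        assert got.shape == (1, 1, 2 * cfg.mlp_width)


class TestProjectBuffer:
    def test_zero_weights_map_padding_to_bias(self, model):
        model.params["proj_w"].data[:] = 0.0
        model.params["proj_b"].data[:] = 0.7
        out = model.project_buffer(np.zeros((2, SMALL.K, (SMALL.T - 1) * SMALL.D),
                                            dtype=np.float32))
        assert np.allclose(out.data, 0.7)       # elu(0.7) = 0.7 > 0

    def test_linearity_before_activation(self, model):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (1, 1, (SMALL.T - 1) * SMALL.D)).astype(np.float32)
        b = rng.normal(0, 1, a.shape).astype(np.float32)
        W = model.params["proj_w"].data
        bias = model.params["proj_b"].data
        pre = lambda x: x @ W + bias
        assert np.allclose(pre(a + b) + pre(np.zeros_like(a)),
                           pre(a) + pre(b), atol=1e-4)

    def test_projection_shape(self, model):
        out = model.project_buffer(np.zeros((4, SMALL.K, (SMALL.T - 1) * SMALL.D),
                                            dtype=np.float32))
        assert out.shape == (4, SMALL.K, SMALL.proj_dim)


class TestStep:
    def test_residual_identity_with_zero_head(self, model):
        model.params["head_w"].data[:] = 0.0
        model.params["head_b"].data[:] = 0.0
        rng = np.random.default_rng(4)
        codes, cams = _rand_inputs(rng, SMALL)
        preds = model.predict(codes[0], cams[0])
        assert np.array_equal(preds, codes[0, :-1])

    def test_output_shape_k_by_d(self, model):
        rng = np.random.default_rng(5)
        codes, cams = _rand_inputs(rng, SMALL)
        preds = model.predict(codes, cams)
        assert preds.shape == (2, SMALL.T - 1, SMALL.K, SMALL.D)

    def test_slot_permutation_equivariance(self, model):
        """Shared weights: permuting slots permutes predictions identically."""
        rng = np.random.default_rng(6)
        codes, cams = _rand_inputs(rng, SMALL, B=1)
        perm = [2, 0, 1]
        base = model.predict(codes[0], cams[0])
        swapped = model.predict(codes[0][:, perm], cams[0])
        assert np.allclose(swapped, base[:, perm], atol=1e-5)

    def test_object_buffer_padding_contract(self):
        buf = ObjectBuffer.empty(K=2, T=4, D=3)
        buf = buf.push(np.ones((2, 3)))
        assert buf.valid_length == 1
        assert (buf.history[:, 1:] == 0).all()
        flat = buf.flat()
        assert flat.shape == (2, 9)


class TestLoss:
    def test_perfect_predictor_zero_loss(self, model):
        model.params["head_w"].data[:] = 0.0
        model.params["head_b"].data[:] = 0.0
        codes = np.ones((1, SMALL.T, SMALL.K, SMALL.D), dtype=np.float32)
        cams = np.zeros((1, SMALL.T, 7), dtype=np.float32)
        assert dynamics_loss(model, codes, cams) == 0.0

    def test_single_step_scalar_arithmetic(self):
        # one slot, scalar codes: z=1 predicted as 0.5 -> squared error 0.25
        assert (1.0 - 0.5) ** 2 == 0.25

    def test_matches_bruteforce_double_loop(self, model):
        rng = np.random.default_rng(7)
        codes, cams = _rand_inputs(rng, SMALL, B=1)
        preds = model.predict(codes[0], cams[0])
        want = 0.0
        for t in range(SMALL.T - 1):
            for k in range(SMALL.K):
                want += ((codes[0, t + 1, k] - preds[t, k]) ** 2).sum()
        got = dynamics_loss(model, codes, cams)
        assert np.isclose(got, want, rtol=1e-4)


class TestParameterAccounting:
    def test_fep_parity_and_fec_surplus_at_paper_dims(self):
        plato = DynamicsConfig.paper()
        assert count_parameters(make_flat_variant("fep")) == count_parameters(plato)
        surplus = count_parameters(make_flat_variant("fec")) - count_parameters(plato)
        assert 2e6 <= surplus <= 8e6          # "approximately four million more"

    def test_analytic_count_equals_allocated(self, model):
        assert count_parameters(SMALL) == model.n_parameters()

    def test_flat_variant_dims(self):
        fep = make_flat_variant("fep")
        fec = make_flat_variant("fec")
        assert fep.K == 1 and fep.D == 16
        assert fec.K == 1 and fec.D == 128
        with pytest.raises(ValueError):
            make_flat_variant("plato")


class TestTraining:
    def test_loss_decreases_on_linear_motion_fixture(self):
        """Codes moving linearly in code space: learnable within 500 steps."""
        rng = np.random.default_rng(0)
        N, cfg = 40, DynamicsConfig(**{**SMALL.__dict__, "lr": 1e-3,
                                       "lr_drop_step": 10 ** 9, "steps": 400,
                                       "batch": 8})
        a = rng.normal(0, 1, (N, 1, cfg.K, cfg.D))
        b = rng.normal(0, 0.15, (N, 1, cfg.K, cfg.D))
        t = np.arange(cfg.T).reshape(1, cfg.T, 1, 1)
        mus = (a + b * t).astype(np.float32)
        lvs = np.full_like(mus, -12.0)
        cams = np.zeros((N, cfg.T, 7), dtype=np.float32)
        _, hist = train_dynamics(mus, lvs, cams, cfg, seed=0)
        assert np.mean(hist[-20:]) < 0.5 * np.mean(hist[:10])

    def test_training_is_seed_deterministic(self):
        cfg = DynamicsConfig(**{**SMALL.__dict__, "steps": 5, "batch": 2})
        rng = np.random.default_rng(1)
        mus = rng.normal(0, 1, (4, cfg.T, cfg.K, cfg.D)).astype(np.float32)
        lvs = np.full_like(mus, -8.0)
        cams = np.zeros((4, cfg.T, 7), dtype=np.float32)
        m1, h1 = train_dynamics(mus, lvs, cams, cfg, seed=9)
        m2, h2 = train_dynamics(mus, lvs, cams, cfg, seed=9)
        assert h1 == h2
        assert np.array_equal(m1.params["head_w"].data, m2.params["head_w"].data)


def test_rollout_continues_after_prefix(model):
    rng = np.random.default_rng(8)
    codes, cams = _rand_inputs(rng, SMALL, B=1)
    out = model.rollout(codes[0, :3], cams[0], n_steps=3)
    assert out.shape == (3, SMALL.K, SMALL.D)
    again = model.rollout(codes[0, :3], cams[0], n_steps=3)
    assert np.array_equal(out, again)
    with pytest.raises(ValueError):
        model.rollout(codes[0, :3], cams[0], n_steps=SMALL.T)


def test_checkpoint_roundtrip(tmp_path, model):
    rng = np.random.default_rng(9)
    codes, cams = _rand_inputs(rng, SMALL, B=1)
    path = tmp_path / "dyn.npz"
    model.save(path)
    loaded = InteractionLSTM.load(path)
    assert np.array_equal(model.predict(codes[0], cams[0]),
                          loaded.predict(codes[0], cams[0]))
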