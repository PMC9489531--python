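"""InteractionLSTM: per-slot recurrent next-step prediction over object codes.

For each slot k the predictor keeps an LSTM state (weights shared across
slots, activations per slot) and sees

* the slot's object buffer — the zero-padded history of its codes over all
  previous frames, flattened and projected to a fixed-size vector through a
  linear map + ELU (padding therefore contributes only the bias);
* an interaction term: pairwise messages from the slot's previous cell state
  to every slot's previous cell state (MLP rho) and to every slot's
  projected buffer (MLP lambda), with the current camera pose appended to
  each message input; messages are aggregated as concat(sum, max) over all
  pairs (self-pairs included);
* the camera pose at the *next* timestep, so predictions are viewpoint
  conditioned.

The prediction head is linear from the LSTM hidden state with a residual
connection from the slot's current code, so a zeroed head predicts exact
code persistence. Training minimises the teacher-forced sum of squared code
errors over t = 1..T-1 and all K slots.

Flat baselines replace the K object slots with a single whole-scene slot:
FEP keeps the code dimension (equal parameter count — slot weights are
shared, so K never enters the count); FEC matches total representational
capacity with D_flat = K * D, which adds parameters in the buffer projection
and prediction head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class DynamicsConfig:
    variant: str = "plato"          # plato | fep | fec
    K: int = 8
    D: int = 16
    H: int = 2056                   # LSTM hidden units
    proj_dim: int = 1680            # object-buffer projection size
    mlp_width: int = 512            # interaction MLP width (= message dim)
    mlp_layers: int = 3
    cam_embed: int = 32
    T: int = 15
    lr: float = 1e-4
    lr_after_drop: float = 4e-5
    lr_drop_step: int = 300_000
    steps: int = 1_300_000
    batch: int = 128

    @staticmethod
    def paper() -> "DynamicsConfig":
        return DynamicsConfig()

    @staticmethod
    def desk() -> "DynamicsConfig":
        """CPU-scale profile; documented as not a replication of full scale."""
        return DynamicsConfig(K=4, D=8, H=160, proj_dim=96, mlp_width=48,
                              mlp_layers=2, cam_embed=8, lr=3e-4,
                              lr_after_drop=1.2e-4, lr_drop_step=900,
                              steps=1300, batch=8)


def make_flat_variant(kind: str, base: DynamicsConfig | None = None
                      ) -> DynamicsConfig:
    """Single-slot baseline configs: 'fep' (equal parameters) or 'fec'
    (equal representational capacity, D_flat = K * D)."""
    base = base or DynamicsConfig.paper()
    if kind == "fep":
        return replace(base, variant="fep", K=1, D=base.D)
    if kind == "fec":
        return replace(base, variant="fec", K=1, D=base.K * base.D)
    raise ValueError("kind must be 'fep' or 'fec'")


def count_parameters(config: DynamicsConfig) -> int:
    """Exact trainable-parameter count of the dynamics predictor.

    Slot weights are shared, so K does not appear: the flat
    equal-parameter baseline matches the slotted model exactly.
    """
    c = config
    E, P, W, H, D = c.cam_embed, c.proj_dim, c.mlp_width, c.H, c.D
    hist = (c.T - 1) * D

    def mlp(in_dim):
        n = in_dim * W + W
        n += (c.mlp_layers - 1) * (W * W + W)
        return n

    total = 7 * E + E                       # camera embedding
    total += hist * P + P                   # buffer projection
    total += mlp(2 * H + E)                 # rho: (from cell, to cell, camera)
    total += mlp(H + P + E)                 # lambda: (from cell, to buffer, camera)
    lstm_in = P + 2 * W + E
    total += lstm_in * 4 * H + H * 4 * H + 4 * H
    total += H * D + D                      # prediction head (+ residual, no params)
    return total


@dataclass
class ObjectBuffer:
    """Zero-padded per-slot code history; padding sits at the future end."""
    history: np.ndarray           # (K, T-1, D)
    valid_length: int

    @classmethod
    def empty(cls, K: int, T: int, D: int) -> "ObjectBuffer":
        return cls(np.zeros((K, T - 1, D), dtype=np.float32), 0)

    def push(self, codes: np.ndarray) -> "ObjectBuffer":
        if self.valid_length >= self.history.shape[1]:
            raise ValueError("buffer full")
        new = self.history.copy()
        new[:, self.valid_length] = codes
        return ObjectBuffer(new, self.valid_length + 1)

    def flat(self) -> np.ndarray:
        K = self.history.shape[0]
        return self.history.reshape(K, -1)


@dataclass
class SlotState:
    cell: np.ndarray              # (K, H)
    hidden: np.ndarray            # (K, H)


class InteractionLSTM:
    """The trainable dynamics predictor (PLATO and flat variants)."""

    def __init__(self, config: DynamicsConfig, seed: int = 0):
        self.config = c = config
        rng = np.random.default_rng(seed)
        E, P, W, H, D = c.cam_embed, c.proj_dim, c.mlp_width, c.H, c.D
        hist = (c.T - 1) * D
        p: dict[str, Tensor] = {}
        p["cam_w"] = ad.glorot(rng, 7, E)
        p["cam_b"] = ad.parameter(np.zeros(E))
        p["proj_w"] = ad.glorot(rng, hist, P)
        p["proj_b"] = ad.parameter(np.zeros(P))
        for name, in_dim in (("rho", 2 * H + E), ("lam", H + P + E)):
            dims = [in_dim] + [W] * c.mlp_layers
            for i in range(c.mlp_layers):
                p[f"{name}_w{i}"] = ad.glorot(rng, dims[i], dims[i + 1])
                p[f"{name}_b{i}"] = ad.parameter(np.zeros(dims[i + 1]))
        lstm_in = P + 2 * W + E
        p["lstm_wx"] = ad.glorot(rng, lstm_in, 4 * H)
        p["lstm_wh"] = ad.glorot(rng, H, 4 * H)
        p["lstm_b"] = ad.parameter(np.zeros(4 * H))
        p["head_w"] = ad.glorot(rng, H, D)
        p["head_b"] = ad.parameter(np.zeros(D))
        self.params = p

    # -- components -------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(int(np.prod(t.shape)) for t in self.params.values())

    def _mlp(self, x: Tensor, name: str) -> Tensor:
        for i in range(self.config.mlp_layers):
            x = (x @ self.params[f"{name}_w{i}"]
                 + self.params[f"{name}_b{i}"]).gelu()
        return x

    def _embed_cam(self, cam: np.ndarray | Tensor) -> Tensor:
        cam = cam if isinstance(cam, Tensor) else ad.constant(cam)
        return cam @ self.params["cam_w"] + self.params["cam_b"]

    def project_buffer(self, buffer_flat) -> Tensor:
        """(..., (T-1)*D) zero-padded flat histories -> (..., proj_dim), ELU."""
        buf = buffer_flat if isinstance(buffer_flat, Tensor) \
            else ad.constant(buffer_flat)
        return (buf @ self.params["proj_w"] + self.params["proj_b"]).elu()

    def interaction(self, cells: Tensor, buf_proj: Tensor,
                    cam_now) -> Tensor:
        """Pairwise messages from each slot to all cells and buffers.

        cells (B,K,H), buf_proj (B,K,P), cam_now (B,7) -> (B,K,2*width),
        aggregated as concat(sum, max) over the 2K "to" elements.
        """
        c = self.config
        B, K, H = cells.shape
        E, P, W = c.cam_embed, c.proj_dim, c.mlp_width
        cam_e = self._embed_cam(cam_now)
        z_to = np.zeros((1, 1, K, 1), dtype=np.float32)
        z_from = np.zeros((1, K, 1, 1), dtype=np.float32)
        z_pair = np.zeros((1, K, K, 1), dtype=np.float32)
        frm = cells.reshape(B, K, 1, H) + z_to
        to_c = cells.reshape(B, 1, K, H) + z_from
        to_b = buf_proj.reshape(B, 1, K, P) + z_from
        cam_p = cam_e.reshape(B, 1, 1, E) + z_pair
        rho_in = ad.concat([frm, to_c, cam_p], axis=-1).reshape(B * K * K, 2 * H + E)
        lam_in = ad.concat([frm, to_b, cam_p], axis=-1).reshape(B * K * K, H + P + E)
        rho = self._mlp(rho_in, "rho").reshape(B, K, K, W)
        lam = self._mlp(lam_in, "lam").reshape(B, K, K, W)
        msgs = ad.concat([rho, lam], axis=2)            # (B, K, 2K, W)
        return ad.concat([msgs.sum(axis=2), msgs.max(axis=2)], axis=-1)

    def step(self, codes_t, buffer_flat, cell: Tensor, hidden: Tensor,
             cam_now, cam_next) -> tuple[Tensor, Tensor, Tensor]:
        """One prediction step for all slots.

        codes_t (B,K,D) current codes; buffer_flat (B,K,(T-1)*D) includes the
        current frame; returns (prediction for t+1, new cell, new hidden).
        """
        c = self.config
        B, K, D = codes_t.shape[:3] if isinstance(codes_t, np.ndarray) \
            else codes_t.shape
        H = c.H
        bp = self.project_buffer(buffer_flat)
        itk = self.interaction(cell, bp, cam_now)
        cam_e = self._embed_cam(cam_next)
        cam_tile = cam_e.reshape(B, 1, c.cam_embed) \
            + np.zeros((1, K, 1), dtype=np.float32)
        x = ad.concat([bp, itk, cam_tile], axis=-1).reshape(B * K, -1)
        gates = x @ self.params["lstm_wx"] \
            + hidden.reshape(B * K, H) @ self.params["lstm_wh"] \
            + self.params["lstm_b"]
        i = gates[:, :H].sigmoid()
        f = gates[:, H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:].sigmoid()
        new_cell = f * cell.reshape(B * K, H) + i * g
        new_hidden = o * new_cell.tanh()
        pred = (new_hidden @ self.params["head_w"] + self.params["head_b"]
                ).reshape(B, K, D)
        codes_t = codes_t if isinstance(codes_t, Tensor) else ad.constant(codes_t)
        pred = pred + codes_t                      # residual from z_k^t
        return pred, new_cell.reshape(B, K, H), new_hidden.reshape(B, K, H)

    # -- sequence processing ---------------------------------------------
    def forward(self, codes: np.ndarray, cams: np.ndarray) -> Tensor:
        """Teacher-forced predictions for frames 2..T: (B,T-1,K,D) Tensor."""
        c = self.config
        B, T, K, D = codes.shape
        cell = ad.constant(np.zeros((B, K, c.H), dtype=np.float32))
        hidden = ad.constant(np.zeros((B, K, c.H), dtype=np.float32))
        buf = np.zeros((B, K, (c.T - 1) * D), dtype=np.float32)
        preds = []
        for t in range(T - 1):
            buf[:, :, t * D:(t + 1) * D] = codes[:, t]
            pred, cell, hidden = self.step(codes[:, t], buf.copy(), cell, hidden,
                                           cams[:, t], cams[:, t + 1])
            preds.append(pred)
        return ad.stack(preds, axis=1)

    def predict(self, codes: np.ndarray, cams: np.ndarray) -> np.ndarray:
        """Inference: (T,K,D) or (B,T,K,D) codes -> predicted codes, numpy."""
        single = codes.ndim == 3
        if single:
            codes, cams = codes[None], cams[None]
        flags = [(p, p.requires_grad) for p in self.params.values()]
        for p, _ in flags:
            p.requires_grad = False
        try:
            out = self.forward(codes.astype(np.float32),
                               cams.astype(np.float32)).data
        finally:
            for p, flag in flags:
                p.requires_grad = flag
        return out[0] if single else out

    def rollout(self, codes_prefix: np.ndarray, cams: np.ndarray,
                n_steps: int) -> np.ndarray:
        """Closed-loop prediction after a teacher-forced prefix (diagnostics).

        codes_prefix (T0,K,D); cams must cover T0 + n_steps frames. Returns
        the (n_steps,K,D) continuation fed back on itself.
        """
        c = self.config
        T0, K, D = codes_prefix.shape
        if T0 + n_steps > c.T:
            raise ValueError("rollout exceeds the model's horizon")
        flags = [(p, p.requires_grad) for p in self.params.values()]
        for p, _ in flags:
            p.requires_grad = False
        try:
            cell = ad.constant(np.zeros((1, K, c.H), dtype=np.float32))
            hidden = ad.constant(np.zeros((1, K, c.H), dtype=np.float32))
            buf = np.zeros((1, K, (c.T - 1) * D), dtype=np.float32)
            current = codes_prefix[0]
            out = []
            for t in range(T0 + n_steps - 1):
                buf[0, :, t * D:(t + 1) * D] = current
                pred, cell, hidden = self.step(
                    current[None].astype(np.float32), buf.copy(), cell, hidden,
                    cams[t][None], cams[t + 1][None])
                nxt = pred.data[0]
                if t + 1 < T0:
                    current = codes_prefix[t + 1]
                else:
                    current = nxt
                    out.append(nxt)
        finally:
            for p, flag in flags:
                p.requires_grad = flag
        return np.array(out)

    def loss(self, codes: np.ndarray, cams: np.ndarray) -> Tensor:
        """Mean-per-video teacher-forced sum of squared code errors."""
        preds = self.forward(codes, cams)
        target = ad.constant(codes[:, 1:])
        return ((preds - target) ** 2).sum() * (1.0 / codes.shape[0])

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, __config__=json.dumps(asdict(self.config)),
                            **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "InteractionLSTM":
        with np.load(path, allow_pickle=False) as z:
            cfg = DynamicsConfig(**json.loads(str(z["__config__"])))
            model = cls(cfg, seed=0)
            for k in model.params:
                model.params[k].data = z[k].astype(np.float32)
        return model


def dynamics_loss(model: InteractionLSTM, video_codes: np.ndarray,
                  cams: np.ndarray) -> float:
    """Scalar teacher-forced loss for one video (T,K,D) or batch (B,T,K,D)."""
    if video_codes.ndim == 3:
        video_codes, cams = video_codes[None], cams[None]
    return float(model.loss(video_codes.astype(np.float32),
                            cams.astype(np.float32)).data)


def train_dynamics(code_means: np.ndarray, code_logvars: np.ndarray,
                   cams: np.ndarray, config: DynamicsConfig, seed: int = 0,
                   log_every: int = 0) -> tuple[InteractionLSTM, list[float]]:
    """Train on encoded videos with teacher forcing.

    code_means/logvars: (N,T,K,D) frozen-encoder posteriors; a fresh
    posterior sample is drawn for every video each iteration (sampled codes
    empirically beat means). The learning rate drops once at lr_drop_step,
    mirroring the two-phase schedule of the full-scale recipe.
    """
    rng = np.random.default_rng(seed)
    model = InteractionLSTM(config, seed=seed)
    opt = ad.RMSProp(model.params.values(), lr=config.lr)
    N = code_means.shape[0]
    history = []
    for step in range(config.steps):
        if step == config.lr_drop_step:
            opt.lr = config.lr_after_drop
        idx = rng.integers(0, N, size=min(config.batch, N))
        mu, lv = code_means[idx], code_logvars[idx]
        z = mu + np.exp(0.5 * lv) * rng.standard_normal(mu.shape)
        loss = model.loss(z.astype(np.float32), cams[idx].astype(np.float32))
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if log_every and step % log_every == 0:
            print(f"[dynamics] step {step} loss {loss.data:.3f}")
    return model, history
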