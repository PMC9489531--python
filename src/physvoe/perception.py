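"""Slotted variational autoencoder over (image, mask) pairs.

Each of the K mask channels selects one object's visible pixels; the encoder
maps that masked view to a D-dimensional diagonal-Gaussian posterior, and a
spatial-broadcast decoder maps a code sample back to an object image and a
mask. Non-floor slots share encoder/decoder weights (so outputs are
equivariant to channel permutation); the floor channel has its own parameter
set, since the ground plane behaves statistically unlike the movable
objects. K posteriors are always produced: empty channels are trained to
reconstruct an all-zero object image and mask, which drives their codes
toward the unit-Gaussian prior.

The training objective per slot is

    ||x_k - x̂_k||^2  +  γ · BCE(m̂_k, m_k)  +  β · KL(q(z_k|x_k,m_k) ‖ N(0,I))

with β = 0.1 and γ = 10 by default — a Gaussian image likelihood with fixed
unit scale, a γ-weighted mask cross-entropy so masks are reconstructed with
high fidelity, and a β-weighted KL. Training uses RMSProp; object codes used
downstream are posterior samples (which empirically beat means for next-step
prediction), with the seed recorded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .world import VideoRecord


@dataclass
class PerceptionConfig:
    H: int = 64
    W: int = 64
    K: int = 8
    D: int = 16
    enc_hidden: int = 256
    dec_hidden: int = 96
    beta: float = 0.1
    gamma: float = 10.0
    lr: float = 1e-4
    steps: int = 1_000_000
    batch: int = 64

    @staticmethod
    def desk() -> "PerceptionConfig":
        """Desk-scale profile: runs end-to-end on one CPU. Not a replication
        of the full-scale configuration (64x64, K=8, D=16, 1e6 steps)."""
        return PerceptionConfig(H=32, W=32, K=4, D=8, enc_hidden=160,
                                dec_hidden=64, lr=1e-3, steps=1800, batch=16)


@dataclass
class SlotPosterior:
    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.mean).all()
                and np.isfinite(self.log_variance).all()):
            raise ValueError("posterior parameters must be finite")


def sample_code(posterior: SlotPosterior, rng: np.random.Generator) -> np.ndarray:
    """Reparameterized draw z = mu + sigma * eps, eps ~ N(0, I)."""
    eps = rng.standard_normal(posterior.mean.shape)
    return posterior.mean + np.exp(0.5 * posterior.log_variance) * eps


@dataclass
class ObjectCodes:
    codes: np.ndarray          # (K, D)
    floor_slot: int = 0


class ComponentVAE:
    """Shared-weight slot encoder/decoder with a dedicated floor slot."""

    N_COORD = 10          # x, y and two Fourier octaves of each

    def __init__(self, config: PerceptionConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        in_dim = c.H * c.W * 4        # masked RGB + the mask itself
        self.params: dict[str, Tensor] = {}
        for tag in ("obj", "floor"):
            self.params[f"enc_w1_{tag}"] = ad.glorot(rng, in_dim, c.enc_hidden)
            self.params[f"enc_b1_{tag}"] = ad.parameter(np.zeros(c.enc_hidden))
            self.params[f"enc_mu_{tag}"] = ad.glorot(rng, c.enc_hidden, c.D)
            self.params[f"enc_bmu_{tag}"] = ad.parameter(np.zeros(c.D))
            self.params[f"enc_lv_{tag}"] = ad.glorot(rng, c.enc_hidden, c.D)
            self.params[f"enc_blv_{tag}"] = ad.parameter(np.zeros(c.D))
            self.params[f"dec_w1_{tag}"] = ad.glorot(rng, c.D + self.N_COORD,
                                                     c.dec_hidden)
            self.params[f"dec_b1_{tag}"] = ad.parameter(np.zeros(c.dec_hidden))
            self.params[f"dec_out_{tag}"] = ad.glorot(rng, c.dec_hidden, 4)
            self.params[f"dec_bout_{tag}"] = ad.parameter(np.zeros(4))
        ys, xs = np.meshgrid(np.linspace(-1, 1, c.H), np.linspace(-1, 1, c.W),
                             indexing="ij")
        # linear + Fourier coordinate channels: with a shallow broadcast
        # decoder, the periodic features make localized bumps (and periodic
        # textures like the checkerboard) linearly accessible
        feats = [xs, ys]
        for f in (np.pi, 2 * np.pi):
            feats += [np.sin(f * xs), np.cos(f * xs),
                      np.sin(f * ys), np.cos(f * ys)]
        self._coords = np.stack(feats, axis=-1).reshape(-1, self.N_COORD) \
            .astype(np.float32)

    # -- forward pieces ---------------------------------------------------
    def _encode_rows(self, rows: Tensor, tag: str) -> tuple[Tensor, Tensor]:
        p = self.params
        h = (rows @ p[f"enc_w1_{tag}"] + p[f"enc_b1_{tag}"]).relu()
        mu = h @ p[f"enc_mu_{tag}"] + p[f"enc_bmu_{tag}"]
        lv = h @ p[f"enc_lv_{tag}"] + p[f"enc_blv_{tag}"]
        return mu, lv

    def encode_t(self, images: np.ndarray, masks: np.ndarray
                 ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Graph-building encode of a batch: (B,H,W,3) x (B,K,H,W) -> posteriors.

        Returns (mu_obj, lv_obj, mu_floor, lv_floor) with object slots flattened
        to (B*(K-1), D) and floor to (B, D).
        """
        c = self.config
        B = images.shape[0]
        masked = images[:, None] * masks[..., None]       # (B,K,H,W,3)
        rows = np.concatenate([masked.reshape(B, c.K, -1),
                               masks.reshape(B, c.K, -1)], axis=-1)
        rows = rows.astype(np.float32)
        in_dim = c.H * c.W * 4
        obj_rows = ad.constant(rows[:, 1:].reshape(B * (c.K - 1), in_dim))
        floor_rows = ad.constant(rows[:, 0])
        mu_o, lv_o = self._encode_rows(obj_rows, "obj")
        mu_f, lv_f = self._encode_rows(floor_rows, "floor")
        return mu_o, lv_o, mu_f, lv_f

    def encode(self, image: np.ndarray, masks: np.ndarray) -> list[SlotPosterior]:
        """K slot posteriors for one frame (image in [0,1], binary masks)."""
        if image.shape[:2] != (self.config.H, self.config.W):
            raise ValueError("image shape mismatch")
        if masks.shape != (self.config.K, self.config.H, self.config.W):
            raise ValueError("mask shape mismatch")
        mu_o, lv_o, mu_f, lv_f = self.encode_t(image[None], masks[None])
        out = [SlotPosterior(mu_f.data[0].copy(), lv_f.data[0].copy())]
        for k in range(self.config.K - 1):
            out.append(SlotPosterior(mu_o.data[k].copy(), lv_o.data[k].copy()))
        return out

    def _encode_rows_np(self, rows: np.ndarray, tag: str
                        ) -> tuple[np.ndarray, np.ndarray]:
        p = {k: v.data for k, v in self.params.items()}
        h = np.maximum(rows @ p[f"enc_w1_{tag}"] + p[f"enc_b1_{tag}"], 0.0)
        return (h @ p[f"enc_mu_{tag}"] + p[f"enc_bmu_{tag}"],
                h @ p[f"enc_lv_{tag}"] + p[f"enc_blv_{tag}"])

    def encode_video(self, video: VideoRecord | tuple[np.ndarray, np.ndarray]
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Posterior (means, log-variances) for every frame: (T,K,D) each."""
        if isinstance(video, VideoRecord):
            frames, masks = video.frames, video.masks
        else:
            frames, masks = video
        c = self.config
        T = frames.shape[0]
        if c.K == 1:
            # flat (whole-scene) model: a single channel uniformly filled
            # with 1 — no segmentation information reaches the encoder
            masks = np.ones((T, 1) + frames.shape[1:3], dtype=np.float32)
        imgs = frames.astype(np.float32) / 255.0
        m = masks.astype(np.float32)
        masked = imgs[:, None] * m[..., None]
        rows = np.concatenate([masked.reshape(T, c.K, -1),
                               m.reshape(T, c.K, -1)], axis=-1).astype(np.float32)
        in_dim = c.H * c.W * 4
        mu_o, lv_o = self._encode_rows_np(
            rows[:, 1:].reshape(T * (c.K - 1), in_dim), "obj")
        mu_f, lv_f = self._encode_rows_np(rows[:, 0], "floor")
        mu = np.concatenate([mu_f[:, None],
                             mu_o.reshape(T, c.K - 1, c.D)], axis=1)
        lv = np.concatenate([lv_f[:, None],
                             lv_o.reshape(T, c.K - 1, c.D)], axis=1)
        return mu, lv

    def _decode_rows(self, codes: Tensor, tag: str) -> tuple[Tensor, Tensor]:
        """Spatial broadcast: (N,D) -> rgb (N,HW,3), mask logits (N,HW).

        The code is broadcast over the pixel grid with coordinate channels;
        since the first layer is linear in [z, x, y], the coordinate part is
        a fixed per-pixel projection computed once per forward pass.
        """
        c = self.config
        n_pix = c.H * c.W
        p = self.params
        N = codes.shape[0]
        w1 = p[f"dec_w1_{tag}"]
        z_proj = codes @ w1[:c.D]                          # (N, h)
        coord_proj = ad.constant(self._coords) @ w1[c.D:]  # (n_pix, h)
        h = (z_proj.reshape(N, 1, c.dec_hidden) + coord_proj.reshape(1, n_pix, c.dec_hidden)
             + p[f"dec_b1_{tag}"]).relu()
        out = h.reshape(N * n_pix, c.dec_hidden) @ p[f"dec_out_{tag}"] \
            + p[f"dec_bout_{tag}"]
        out = out.reshape(N, n_pix, 4)
        rgb = out[:, :, :3].sigmoid()
        logit = out[:, :, 3]
        return rgb, logit

    def _decode_rows_np(self, codes: np.ndarray, tag: str
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Inference-only decoder forward pass (no graph, chunked, in-place)."""
        c = self.config
        n_pix = c.H * c.W
        p = {k: v.data for k, v in self.params.items()}
        N = codes.shape[0]
        w1 = p[f"dec_w1_{tag}"]
        z_proj = codes @ w1[:c.D] + p[f"dec_b1_{tag}"]
        coord_proj = self._coords @ w1[c.D:]
        out = np.empty((N, n_pix, 4), dtype=np.float32)
        chunk = max(1, (1 << 26) // (n_pix * c.dec_hidden))   # ~256 MB scratch
        buf = np.empty((min(chunk, N), n_pix, c.dec_hidden), dtype=np.float32)
        for i in range(0, N, chunk):
            n = min(chunk, N - i)
            b = buf[:n]
            np.add(z_proj[i:i + n, None, :], coord_proj[None], out=b)
            np.maximum(b, 0.0, out=b)
            out[i:i + n] = (b.reshape(n * n_pix, c.dec_hidden)
                            @ p[f"dec_out_{tag}"]).reshape(n, n_pix, 4)
        out += p[f"dec_bout_{tag}"]
        rgb = out[:, :, :3]
        np.negative(rgb, out=rgb)
        np.exp(rgb, out=rgb)
        rgb += 1.0
        np.reciprocal(rgb, out=rgb)
        return np.ascontiguousarray(rgb), out[:, :, 3]

    def decode(self, code: np.ndarray, slot: str = "obj"
               ) -> tuple[np.ndarray, np.ndarray]:
        """One code -> (object image (H,W,3), mask logits (H,W))."""
        c = self.config
        rgb, logit = self._decode_rows_np(code[None].astype(np.float32), slot)
        return rgb[0].reshape(c.H, c.W, 3), logit[0].reshape(c.H, c.W)

    def decode_slots(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(N,K,D) codes -> rgb (N,K,HW,3) and mask probabilities (N,K,HW)."""
        c = self.config
        N = codes.shape[0]
        codes = codes.astype(np.float32, copy=False)
        rgb_f, log_f = self._decode_rows_np(codes[:, 0], "floor")
        rgb_o, log_o = self._decode_rows_np(
            codes[:, 1:].reshape(N * (c.K - 1), c.D), "obj")
        n_pix = c.H * c.W
        rgb = np.concatenate([rgb_f[:, None],
                              rgb_o.reshape(N, c.K - 1, n_pix, 3)], axis=1)
        logit = np.concatenate([log_f[:, None],
                                log_o.reshape(N, c.K - 1, n_pix)], axis=1)
        return rgb, 1.0 / (1.0 + np.exp(-logit))

    def object_views(self, codes: np.ndarray) -> np.ndarray:
        """Decoded per-object views Θ(z) = x̂_k ⊙ m̂_k, shape (N,K,HW,3)."""
        rgb, m = self.decode_slots(codes)
        return rgb * m[..., None]

    def reconstruct_scene(self, codes: np.ndarray) -> np.ndarray:
        """Compose K decoded slots into one image using decoded mask weights."""
        rgb, m = self.decode_slots(codes[None])
        w = m[0] / np.maximum(m[0].sum(axis=0, keepdims=True), 1e-6)
        img = (rgb[0] * w[..., None]).sum(axis=0)
        c = self.config
        return np.clip(img, 0.0, 1.0).reshape(c.H, c.W, 3)

    # -- objective --------------------------------------------------------
    def loss(self, images: np.ndarray, masks: np.ndarray,
             rng: np.random.Generator) -> Tensor:
        """Mean per-image variational objective over a batch of frames."""
        c = self.config
        B = images.shape[0]
        n_pix = c.H * c.W
        mu_o, lv_o, mu_f, lv_f = self.encode_t(images, masks)
        total = None
        for tag, mu, lv, sl in (("floor", mu_f, lv_f, slice(0, 1)),
                                ("obj", mu_o, lv_o, slice(1, None))):
            n_slots = 1 if tag == "floor" else c.K - 1
            eps = rng.standard_normal((B * n_slots, c.D)).astype(np.float32)
            z = mu + (lv * 0.5).exp() * eps
            rgb, logit = self._decode_rows(z, tag)
            target_m = masks[:, sl].reshape(B * n_slots, n_pix).astype(np.float32)
            target_x = (images[:, None] * masks[..., None])[:, sl]
            target_x = target_x.reshape(B * n_slots, n_pix, 3).astype(np.float32)
            recon = ((rgb - target_x) ** 2).sum()
            mask_bce = logit.bce_with_logits(target_m).sum()
            kl = (0.5 * ((mu ** 2) + lv.exp() - lv - 1.0)).sum()
            term = recon + c.gamma * mask_bce + c.beta * kl
            total = term if total is None else total + term
        return total * (1.0 / B)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, __config__=json.dumps(asdict(self.config)),
                            **{k: v.data for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "ComponentVAE":
        with np.load(path, allow_pickle=False) as z:
            cfg = PerceptionConfig(**json.loads(str(z["__config__"])))
            model = cls(cfg, seed=0)
            for k in model.params:
                model.params[k].data = z[k].astype(np.float32)
        return model


def perception_loss(model: ComponentVAE, images: np.ndarray, masks: np.ndarray,
                    seed: int = 0) -> float:
    """Scalar objective on a batch (frames in [0,1], binary masks)."""
    return float(model.loss(images, masks, np.random.default_rng(seed)).data)


def train_perception(videos, config: PerceptionConfig, seed: int = 0,
                     log_every: int = 0) -> tuple[ComponentVAE, list[float]]:
    """Train a ComponentVAE on frames sampled from `videos`; returns it frozen.

    `videos` is a sequence of VideoRecords or (frames, masks) pairs. The
    full-scale recipe (1e6 steps, batch 64, lr 1e-4) is the config default;
    the desk profile reduces steps and resolution.
    """
    frames = []
    masks = []
    for v in videos:
        f, m = (v.frames, v.masks) if isinstance(v, VideoRecord) else v
        frames.append(f)
        masks.append(m)
    frames = np.concatenate(frames).astype(np.float32) / 255.0
    masks = np.concatenate(masks).astype(np.float32)
    if config.K == 1:       # flat model: one all-ones channel, no segmentation
        masks = np.ones((len(frames), 1) + frames.shape[1:3], dtype=np.float32)

    rng = np.random.default_rng(seed)
    model = ComponentVAE(config, seed=seed)
    opt = ad.RMSProp(model.params.values(), lr=config.lr)
    history = []
    for step in range(config.steps):
        idx = rng.integers(0, len(frames), size=config.batch)
        loss = model.loss(frames[idx], masks[idx], rng)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if log_every and step % log_every == 0:
            print(f"[perception] step {step} loss {loss.data:.1f}")
    return model, history
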