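"""End-to-end desk-scale pipeline: generate, train, probe, evaluate.

Glue shared by the command-line interface, the test suite and the
reproduction script. Every function is a pure function of its seed.
"""

from __future__ import annotations

import time

import numpy as np

from .dynamics import DynamicsConfig, train_dynamics
from .perception import ComponentVAE, PerceptionConfig, train_perception
from .probes import CONCEPTS, ProbeProfile, DESK_PROFILE, generate_probe_tuples
from .world import SceneConfig, sample_freeform_scene, simulate_scene


def generate_freeform_videos(n: int, seed: int, profile: ProbeProfile = DESK_PROFILE,
                             n_steps: int = 450, scene_config: SceneConfig | None = None,
                             log_every: int = 0):
    """n freeform training videos at the given rendering profile."""
    cfg = scene_config or SceneConfig(K=profile.K)
    seq = np.random.SeedSequence(seed)
    vids = []
    t0 = time.time()
    for i, s in enumerate(seq.generate_state(n).astype(np.int64)):
        vids.append(simulate_scene(sample_freeform_scene(int(s) & 0x7FFFFFFF, cfg),
                                   n_steps=n_steps, T=profile.T,
                                   H=profile.H, W=profile.W, K=profile.K))
        if log_every and (i + 1) % log_every == 0:
            print(f"[generate] {i + 1}/{n} videos ({time.time() - t0:.0f}s)")
    return vids


def encode_videos(videos, perception: ComponentVAE):
    """Frozen-encoder posteriors and cameras for a video list: (N,T,K,D) x2, (N,T,7)."""
    mus, lvs, cams = [], [], []
    for v in videos:
        mu, lv = perception.encode_video(v)
        mus.append(mu)
        lvs.append(lv)
        cams.append(v.camera.encode())
    return (np.stack(mus).astype(np.float32), np.stack(lvs).astype(np.float32),
            np.stack(cams).astype(np.float32))


def train_desk_models(videos, seed: int = 0,
                      perception_cfg: PerceptionConfig | None = None,
                      dynamics_cfg: DynamicsConfig | None = None,
                      n_dynamics_seeds: int = 1, log_every: int = 0):
    """Two-phase training: perception first, frozen; then dynamics per seed."""
    pcfg = perception_cfg or PerceptionConfig.desk()
    dcfg = dynamics_cfg or DynamicsConfig.desk()
    perception, p_hist = train_perception(videos, pcfg, seed=seed,
                                          log_every=log_every)
    mus, lvs, cams = encode_videos(videos, perception)
    dyn_models = []
    d_hists = []
    for s in range(n_dynamics_seeds):
        dyn, d_hist = train_dynamics(mus, lvs, cams, dcfg, seed=seed + 101 * s,
                                     log_every=log_every)
        dyn_models.append(dyn)
        d_hists.append(d_hist)
    return perception, dyn_models, {"perception_loss": p_hist,
                                    "dynamics_loss": d_hists}


def generate_probe_sets(n_per_concept: int, seed: int,
                        profile: ProbeProfile = DESK_PROFILE,
                        concepts=CONCEPTS, log_every: int = 0):
    """Verified probe tuples for each concept: {concept: [ProbeTuple]}."""
    out = {}
    for i, c in enumerate(concepts):
        t0 = time.time()
        out[c] = generate_probe_tuples(c, n_per_concept, seed + 17 * i, profile)
        if log_every:
            print(f"[probes] {c}: {n_per_concept} tuples ({time.time() - t0:.0f}s)")
    return out
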