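"""Shared fixtures: tiny deterministic scenes and trained desk-scale models.

The heavyweight `desk_run` fixture executes the whole desk-scale study once
per session (freeform corpus -> perception -> dynamics -> probe sets) and is
shared by every test that needs trained models or large probe batches.
"""

from __future__ import annotations

import numpy as np
import pytest

from physvoe.data import make_fixtures
from physvoe.dynamics import DynamicsConfig
from physvoe.perception import PerceptionConfig
from physvoe.pipeline import (generate_freeform_videos, generate_probe_sets,
                              train_desk_models)

# study conditions for the desk-scale run (chosen once; documented in
# docs/methods.md): 2000 training videos, desk profiles, 200 tuples/concept
DESK_SEED_VIDEOS = 11
DESK_SEED_TRAIN = 0
DESK_SEED_PROBES = 23
DESK_SEED_EVAL = 7
DESK_N_VIDEOS = 2000
DESK_N_TUPLES = 200


@pytest.fixture(scope="session")
def fx():
    """Tiny deterministic scenes, videos and one probe tuple per concept."""
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def mini_models():
    """A small trained model pair for unit-level behavioural tests."""
    videos = generate_freeform_videos(60, seed=1)
    pcfg = PerceptionConfig.desk()
    pcfg.steps = 300
    dcfg = DynamicsConfig.desk()
    dcfg.steps = 250
    dcfg.lr_drop_step = 180
    perception, dyn_models, hist = train_desk_models(
        videos, seed=0, perception_cfg=pcfg, dynamics_cfg=dcfg)
    return {"videos": videos, "perception": perception,
            "dynamics": dyn_models[0], "history": hist}


@pytest.fixture(scope="session")
def desk_run():
    """The full desk-scale study: corpus, trained models, verified probes."""
    videos = generate_freeform_videos(DESK_N_VIDEOS, seed=DESK_SEED_VIDEOS)
    perception, dyn_models, hist = train_desk_models(videos, seed=DESK_SEED_TRAIN)
    probe_sets = generate_probe_sets(DESK_N_TUPLES, seed=DESK_SEED_PROBES)
    return {
        "videos": videos,
        "perception": perception,
        "dynamics": dyn_models[0],
        "history": hist,
        "probe_sets": probe_sets,
        "eval_seed": DESK_SEED_EVAL,
    }


def binomial_bounds(n: int, p: float = 0.5, z: float = 1.96) -> tuple[float, float]:
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
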