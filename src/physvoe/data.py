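"""Dataset serialization, manifests, run profiles and deterministic fixtures.

A dataset is one directory holding a `manifest.json` (schema version, kind,
counts, tensor shapes, per-item seeds, concept tags, generator-config hash)
plus one compressed array bundle per item: `frames` uint8 (T,H,W,3), `masks`
uint8 (T,K,H,W) and `camera` float32 (T,7). Round trips are lossless and
byte-stable: writing the same seed twice produces identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .probes import ProbeTuple, ProbeProfile, DESK_PROFILE, PAPER_PROFILE
from .world import CameraTrack, VideoRecord

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Scale profile bundling every knob of the pipeline.

    The `paper` profile records the full-scale defaults as documentation
    (300k training videos, 64x64, K=8, D=16, LSTM 2056, projection 1680,
    beta 0.1, gamma 10, 1e6 perception steps, 1.3e6 dynamics steps with the
    1e-4 -> 4e-5 learning-rate drop at 300k, batch sizes 64/128). The `desk`
    profile runs end-to-end on one CPU and is NOT a replication of that
    scale.
    """
    profile: str = "desk"
    n_train_videos: int = 2000
    n_probe_tuples: int = 100
    probe: ProbeProfile = field(default_factory=lambda: DESK_PROFILE)
    sim_steps: int = 700
    seconds_per_video: float = 2.0

    @staticmethod
    def paper() -> "RunConfig":
        return RunConfig(profile="paper", n_train_videos=300_000,
                         n_probe_tuples=5000, probe=PAPER_PROFILE,
                         sim_steps=3000)

    @staticmethod
    def desk() -> "RunConfig":
        return RunConfig()


def _save_bundle(path: Path, frames: np.ndarray, masks: np.ndarray,
                 camera: np.ndarray, **extra) -> None:
    np.savez_compressed(path, frames=frames, masks=masks, camera=camera, **extra)


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]


def write_video_dataset(path, videos: list[VideoRecord], kind: str = "freeform",
                        seed: int | None = None, config=None) -> dict:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    items = []
    for i, v in enumerate(videos):
        name = f"video_{i:05d}.npz"
        _save_bundle(path / name, v.frames, v.masks, v.camera.encode())
        items.append({"file": name, "seed": v.meta.get("seed"),
                      "concept": v.meta.get("concept"),
                      "warnings": v.meta.get("warnings", [])})
    manifest = {
        "schema_version": SCHEMA_VERSION, "kind": kind, "count": len(videos),
        "shapes": {"frames": list(videos[0].frames.shape),
                   "masks": list(videos[0].masks.shape)} if videos else {},
        "seed": seed, "config_hash": _config_hash(config), "items": items,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _camera_from_encoded(arr: np.ndarray) -> CameraTrack:
    return CameraTrack(arr[:, :3].astype(float), arr[:, 3:].astype(float))


def read_video_dataset(path) -> tuple[list[VideoRecord], dict]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    videos = []
    for item in manifest["items"]:
        f = path / item["file"]
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file {f}")
        with np.load(f) as z:
            videos.append(VideoRecord(z["frames"], z["masks"],
                                      _camera_from_encoded(z["camera"]),
                                      {"seed": item.get("seed"),
                                       "concept": item.get("concept")}))
    return videos, manifest


def write_probe_dataset(path, tuples: list[ProbeTuple], concept: str,
                        seed: int | None = None, config=None) -> dict:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    items = []
    for i, tup in enumerate(tuples):
        name = f"tuple_{i:05d}.npz"
        vids = tup.all_videos()
        arrays = {}
        for j, v in enumerate(vids):
            arrays[f"frames_{j}"] = v.frames
            arrays[f"masks_{j}"] = v.masks
        np.savez_compressed(path / name, camera=vids[0].camera.encode(),
                            **arrays)
        items.append({"file": name, "seed": tup.seed, "concept": tup.concept,
                      "violation_onset": list(tup.violation_onset),
                      "roles": [v.meta.get("role") for v in vids]})
    manifest = {
        "schema_version": SCHEMA_VERSION, "kind": "probe", "concept": concept,
        "count": len(tuples), "seed": seed, "config_hash": _config_hash(config),
        "shapes": {"frames": list(tuples[0].possible[0].frames.shape),
                   "masks": list(tuples[0].possible[0].masks.shape)} if tuples else {},
        "items": items,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_probe_dataset(path) -> tuple[list[ProbeTuple], dict]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    tuples = []
    for item in manifest["items"]:
        f = path / item["file"]
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing file {f}")
        with np.load(f) as z:
            cam = _camera_from_encoded(z["camera"])
            vids = [VideoRecord(z[f"frames_{j}"], z[f"masks_{j}"], cam,
                                {"role": item["roles"][j],
                                 "concept": item["concept"]})
                    for j in range(4)]
        tuples.append(ProbeTuple(item["concept"], vids[:2], vids[2:],
                                 tuple(item["violation_onset"]),
                                 item.get("seed", 0)))
    return tuples, manifest


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def make_fixtures(seed: int = 0, out_dir=None) -> dict:
    """Tiny deterministic scenes and miniature probe tuples for test suites.

    Returns a dict of in-memory objects; if out_dir is given, also
    serializes them as datasets. Covers: an empty scene, a ballistic drop, a
    roll-and-reflect event, an occlusion pass, and one desk-profile probe
    tuple per concept.
    """
    from .probes import CONCEPTS, make_probe
    from .world import Behavior, BodyState, ObjectSpec, SceneSpec, simulate_scene

    rng = np.random.default_rng(seed)
    floor = (tuple(rng.uniform(0.2, 0.9, 3)), tuple(rng.uniform(0.2, 0.9, 3)))
    H = W = 32

    empty = SceneSpec([], floor, "fixed", seed)
    drop = SceneSpec([(ObjectSpec("sphere", (0.6,) * 3, (0.9, 0.2, 0.2), 40.0, 1),
                       BodyState([0, 0, 2.5], [0, 0, 0]), Behavior("ballistic"))],
                     floor, "fixed", seed)
    reflect = SceneSpec([
        (ObjectSpec("box", (1.2, 0.8, 1.0), (0.2, 0.2, 0.8), 40.0, 1),
         BodyState([0, 1.0, 0.5], np.zeros(3)), Behavior("static")),
        (ObjectSpec("sphere", (0.6,) * 3, (0.9, 0.8, 0.1), 10.0, 2),
         BodyState([-1.5, -1.5, 0.3], [1.5, 1.6, 0.0]), Behavior("rolling"))],
        floor, "fixed", seed)
    occlusion = SceneSpec([
        (ObjectSpec("curtain", (2.0, 0.1, 1.8), (0.3, 0.6, 0.3), 10.0, 1),
         BodyState([0, -0.8, 3.5], np.zeros(3)),
         Behavior("script", {"script": "curtain", "x": 0.0, "y": -0.8,
                             "z_high": 3.5, "z_low": 0.9, "t_down": 0.6,
                             "t_hold_until": 1.2, "t_up_until": 1.9})),
        (ObjectSpec("sphere", (0.7,) * 3, (0.8, 0.3, 0.7), 10.0, 2),
         BodyState([-2.0, 0.5, 0.35], [2.0, 0, 0]), Behavior("rolling"))],
        floor, "fixed", seed)

    scenes = {"empty": empty, "ballistic_drop": drop,
              "roll_and_reflect": reflect, "occlusion_pass": occlusion}
    videos = {name: simulate_scene(sp, n_steps=450, T=10, H=H, W=W, K=4)
              for name, sp in scenes.items()}
    probes = {c: make_probe(c, seed + 7, DESK_PROFILE) for c in CONCEPTS}

    out = {"scenes": scenes, "videos": videos, "probes": probes}
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_video_dataset(out_dir / "scenes", list(videos.values()),
                            kind="fixtures", seed=seed)
        for c, tup in probes.items():
            write_probe_dataset(out_dir / f"probe_{c}", [tup], concept=c,
                                seed=seed)
    return out
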