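"""Procedural rigid-body world: scenes, simplified physics and a raycasting renderer.

The simulator is deliberately small: point-mass translation under gravity,
ground contact with rest, constant-velocity rolling, impulse reflection off
heavy static bodies and a handful of keyframed scripts (curtain descent,
plank overturn, cover drops, ramp rolls, polyline paths). Free flight is
integrated exactly (constant acceleration), so trajectories agree with the
closed-form parabola to float precision. Everything — sampling, simulation,
rendering — is a pure function of (spec, seed), so identical seeds yield
bit-identical videos.

Rendering is a per-pixel raycaster: every pixel is owned by the nearest
primitive along its ray, which directly yields the disjoint per-object mask
channels. Channel 0 is the checkerboard floor plus sky; channels 1..K-1 hold
movable objects, consistently across frames. Composite shapes (curtain, ramp,
arch, containers) decompose into box parts sharing one object id and one
mask channel.

Coordinates are right-handed with z up and the ground plane at z = 0; world
units are arbitrary, gravity defaults to 9.8 units/s^2 over 2 s per video.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Sequence

import numpy as np

G_DEFAULT = 9.8
DURATION_DEFAULT = 2.0
HEAVY_MASS = 20.0      # static bodies at/above this mass reflect impinging spheres
SKY_COLOR = np.array([0.62, 0.79, 0.94])
LIGHT_DIR = np.array([0.35, -0.45, 0.82]) / np.linalg.norm([0.35, -0.45, 0.82])

SHAPES = ("sphere", "box", "curtain", "ramp", "arch",
          "open_container", "closed_container")

# Stereotyped masses for freeform events: rolled/stacked objects are light,
# dropped or thrown objects four times heavier, containers lighter still and
# arches heavy in total so they stay upright.
MASS_ROLLED = 10.0
MASS_DROPPED = 40.0
MASS_CONTAINER = (4.0, 5.0)
MASS_ARCH = 60.0


class GenerationError(RuntimeError):
    """Raised when a scene composition cannot be satisfied within the retry bound."""


# --------------------------------------------------------------------------
# quaternions (w, x, y, z convention)
# --------------------------------------------------------------------------

QUAT_ID = np.array([1.0, 0.0, 0.0, 0.0])


def quat_from_axis_angle(axis: Sequence[float], angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    h = 0.5 * angle
    return np.concatenate([[math.cos(h)], math.sin(h) * axis])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def quat_from_matrix(m: np.ndarray) -> np.ndarray:
    t = np.trace(m)
    if t > 0:
        s = math.sqrt(t + 1.0) * 2
        q = np.array([0.25 * s, (m[2, 1] - m[1, 2]) / s,
                      (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = math.sqrt(max(1.0 + m[i, i] - m[j, j] - m[k, k], 1e-12)) * 2
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    return q / np.linalg.norm(q)


def look_at_quat(position: np.ndarray, target: np.ndarray) -> np.ndarray:
    forward = np.asarray(target, float) - np.asarray(position, float)
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    nr = np.linalg.norm(right)
    if nr < 1e-9:   # looking straight down
        right = np.array([1.0, 0.0, 0.0])
    else:
        right = right / nr
    cam_up = np.cross(right, forward)
    # right-handed camera frame: x right, y up, -z is the viewing direction
    return quat_from_matrix(np.stack([right, cam_up, -forward], axis=1))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ObjectSpec:
    shape: str
    size: tuple[float, float, float]     # full extents per axis (sphere: size[0] = diameter)
    color: tuple[float, float, float]
    mass: float
    object_id: int

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if not all(s > 0 for s in self.size):
            raise ValueError("extents must be strictly positive")
        if not all(0.0 <= c <= 1.0 for c in self.color):
            raise ValueError("color components must be in [0, 1]")
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    def parts(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Decompose into box parts: (local offset, full extents).

        Spheres return an empty list (rendered analytically). All parts share
        this object's id and mask channel.
        """
        sx, sy, sz = self.size
        if self.shape in ("box", "curtain", "ramp"):
            return [(np.zeros(3), np.array(self.size))]
        if self.shape == "arch":
            leg_w = 0.25 * sx
            leg_h = 0.75 * sz
            lint_h = sz - leg_h
            return [
                (np.array([-(sx - leg_w) / 2, 0, -(sz - leg_h) / 2]),
                 np.array([leg_w, sy, leg_h])),
                (np.array([(sx - leg_w) / 2, 0, -(sz - leg_h) / 2]),
                 np.array([leg_w, sy, leg_h])),
                (np.array([0, 0, (sz - lint_h) / 2]), np.array([sx, sy, lint_h])),
            ]
        if self.shape in ("open_container", "closed_container"):
            t = 0.12 * min(sx, sy)          # wall thickness
            base_h = 0.12 * sz
            parts = [
                (np.array([-(sx - t) / 2, 0, 0]), np.array([t, sy, sz])),
                (np.array([(sx - t) / 2, 0, 0]), np.array([t, sy, sz])),
                (np.array([0, -(sy - t) / 2, 0]), np.array([sx - 2 * t, t, sz])),
                (np.array([0, (sy - t) / 2, 0]), np.array([sx - 2 * t, t, sz])),
            ]
            if self.shape == "open_container":   # closed bottom, open top
                parts.append((np.array([0, 0, -(sz - base_h) / 2]),
                              np.array([sx - 2 * t, sy - 2 * t, base_h])))
            else:                                # closed top, open bottom
                parts.append((np.array([0, 0, (sz - base_h) / 2]),
                              np.array([sx - 2 * t, sy - 2 * t, base_h])))
            return parts
        return []


@dataclass
class BodyState:
    position: np.ndarray
    velocity: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: QUAT_ID.copy())

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if not math.isclose(n, 1.0, abs_tol=1e-6):
            raise ValueError("orientation quaternion must be unit norm")


@dataclass
class Behavior:
    """How a body moves: 'static', 'rolling', 'ballistic' or 'script'.

    Scripted kinds close the gap the point-mass core cannot produce
    dynamically (rotating planks, curtains, covers, ramp rolls, exact
    reflection paths); their parameters are plain JSON-serializable values so
    a SceneSpec fully determines the video.
    """
    kind: str = "static"
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class CameraTrack:
    positions: np.ndarray          # (T, 3)
    quats: np.ndarray              # (T, 4)

    def __len__(self):
        return len(self.positions)

    def encode(self) -> np.ndarray:
        """Per-frame 7-vector (position ++ quaternion) for downstream models."""
        return np.concatenate([self.positions, self.quats], axis=1).astype(np.float32)


CANONICAL_CAM_POS = np.array([0.0, -9.0, 3.8])
CANONICAL_CAM_TARGET = np.array([0.0, 0.0, 0.8])


def canonical_camera(T: int, position=None, target=None) -> CameraTrack:
    pos = np.asarray(CANONICAL_CAM_POS if position is None else position, float)
    tgt = np.asarray(CANONICAL_CAM_TARGET if target is None else target, float)
    q = look_at_quat(pos, tgt)
    return CameraTrack(np.tile(pos, (T, 1)), np.tile(q, (T, 1)))


DRIFT_BOUNDS = (CANONICAL_CAM_POS - np.array([1.2, 1.0, 0.8]),
                CANONICAL_CAM_POS + np.array([1.2, 1.0, 0.8]))


def drift_camera(rng_seed: int, T: int, bounds=DRIFT_BOUNDS,
                 step_sigma: float = 0.10) -> CameraTrack:
    """Random-walk camera clipped to a bounding box, starting at the canonical pose.

    The look-at point stays at the scene centre so the view never leaves the
    region of interest; zero-extent bounds therefore yield a constant track.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    lo, hi = (np.asarray(b, float) for b in bounds)
    rng = np.random.default_rng(rng_seed)
    pos = np.empty((T, 3))
    pos[0] = CANONICAL_CAM_POS
    for t in range(1, T):
        pos[t] = np.clip(pos[t - 1] + rng.normal(0.0, step_sigma, 3), lo, hi)
    quats = np.stack([look_at_quat(p, CANONICAL_CAM_TARGET) for p in pos])
    return CameraTrack(pos, quats)


@dataclass
class SceneSpec:
    objects: list[tuple[ObjectSpec, BodyState, Behavior]]
    floor_colors: tuple[tuple[float, float, float], tuple[float, float, float]]
    camera: str | CameraTrack = "fixed"            # "fixed" | "drifting" | explicit track
    seed: int = 0
    gravity: float = G_DEFAULT
    duration: float = DURATION_DEFAULT
    blocks: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        def arr(x):
            return np.asarray(x).tolist()
        return {
            "objects": [
                {"spec": {**asdict(o), "size": list(o.size), "color": list(o.color)},
                 "state": {"position": arr(s.position), "velocity": arr(s.velocity),
                           "orientation": arr(s.orientation)},
                 "behavior": {"kind": b.kind, "params": _jsonable(b.params)}}
                for o, s, b in self.objects
            ],
            "floor_colors": [list(self.floor_colors[0]), list(self.floor_colors[1])],
            "camera": self.camera if isinstance(self.camera, str) else {
                "positions": arr(self.camera.positions), "quats": arr(self.camera.quats)},
            "seed": self.seed, "gravity": self.gravity, "duration": self.duration,
            "blocks": self.blocks,
        }

    @staticmethod
    def from_dict(d: dict) -> "SceneSpec":
        objs = []
        for item in d["objects"]:
            sp = item["spec"]
            objs.append((
                ObjectSpec(sp["shape"], tuple(sp["size"]), tuple(sp["color"]),
                           sp["mass"], sp["object_id"]),
                BodyState(item["state"]["position"], item["state"]["velocity"],
                          item["state"]["orientation"]),
                Behavior(item["behavior"]["kind"], item["behavior"]["params"]),
            ))
        cam = d["camera"]
        if not isinstance(cam, str):
            cam = CameraTrack(np.asarray(cam["positions"]), np.asarray(cam["quats"]))
        return SceneSpec(objs, (tuple(d["floor_colors"][0]), tuple(d["floor_colors"][1])),
                         cam, d["seed"], d["gravity"], d["duration"],
                         d.get("blocks", []))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


@dataclass
class VideoRecord:
    frames: np.ndarray           # (T, H, W, 3) uint8
    masks: np.ndarray            # (T, K, H, W) uint8, channel 0 = floor/sky
    camera: CameraTrack
    meta: dict = field(default_factory=dict)

    @property
    def T(self):
        return self.frames.shape[0]

    def validate(self) -> None:
        T, H, W, _ = self.frames.shape
        assert self.masks.shape[0] == T and self.masks.shape[2:] == (H, W)
        assert self.frames.dtype == np.uint8 and self.masks.dtype == np.uint8
        total = self.masks.sum(axis=1)
        if not (total == 1).all():
            raise AssertionError("mask channels must partition every pixel")
        if len(self.camera) != T:
            raise AssertionError("camera track length mismatch")


def masks_to_labels(masks: np.ndarray) -> np.ndarray:
    """Channel-stacked (T,K,H,W) binary masks -> integer-labelled (T,H,W) plane."""
    return masks.argmax(axis=1).astype(np.uint8)


def labels_to_masks(labels: np.ndarray, K: int) -> np.ndarray:
    T, H, W = labels.shape
    out = np.zeros((T, K, H, W), dtype=np.uint8)
    for k in range(K):
        out[:, k] = labels == k
    return out


# --------------------------------------------------------------------------
# renderer
# --------------------------------------------------------------------------

def _pixel_rays(H: int, W: int, fov_deg: float = 42.0) -> np.ndarray:
    """Camera-frame unit ray directions (H*W, 3): x right, y up, -z viewing."""
    half = math.tan(math.radians(fov_deg) / 2.0)
    xs = (np.arange(W) + 0.5) / W * 2.0 - 1.0
    ys = 1.0 - (np.arange(H) + 0.5) / H * 2.0
    gx, gy = np.meshgrid(xs * half, ys * half)
    d = np.stack([gx, gy, -np.ones_like(gx)], axis=-1).reshape(-1, 3)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def render_frame(bodies: list[dict], camera_pose: tuple[np.ndarray, np.ndarray],
                 floor_colors, H: int = 64, W: int = 64,
                 fov_deg: float = 42.0) -> tuple[np.ndarray, np.ndarray]:
    """Raycast one frame.

    bodies: dicts with keys shape, size, color, position, orientation, channel,
    and optional hidden (bool). Returns (image float in [0,1] of shape (H,W,3),
    owner channel per pixel (H,W) int). Pixel ownership = nearest surface, so
    occluded portions of objects are absent from their channels by construction.
    """
    cam_pos, cam_quat = camera_pose
    R = quat_to_matrix(np.asarray(cam_quat, float))
    dirs = _pixel_rays(H, W, fov_deg) @ R.T          # world-frame directions
    origin = np.asarray(cam_pos, float)

    n_pix = H * W
    depth = np.full(n_pix, np.inf)
    color = np.tile(SKY_COLOR, (n_pix, 1))
    owner = np.zeros(n_pix, dtype=np.int32)

    # floor: checkerboard on z = 0
    dz = dirs[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_floor = -origin[2] / dz
    hit = (t_floor > 1e-6) & (dz < 0)
    if hit.any():
        pts = origin[None, :] + t_floor[hit, None] * dirs[hit]
        cell = 1.6
        parity = (np.floor(pts[:, 0] / cell) + np.floor(pts[:, 1] / cell)).astype(int) % 2
        fc = np.stack([np.asarray(floor_colors[0], float),
                       np.asarray(floor_colors[1], float)])
        base = fc[parity]
        # fade distant floor toward the mean colour: calms horizon aliasing
        fade = np.clip((t_floor[hit] - 14.0) / 22.0, 0.0, 0.85)[:, None]
        depth[hit] = t_floor[hit]
        color[hit] = base * (1 - fade) + fc.mean(axis=0) * fade
        owner[hit] = 0

    for body in bodies:
        if body.get("hidden"):
            continue
        col = np.asarray(body["color"], float)
        ch = body["channel"]
        if body["shape"] == "sphere":
            r = body["size"][0] / 2.0
            c = np.asarray(body["position"], float)
            oc = origin - c
            b = dirs @ oc
            disc = b * b - (oc @ oc - r * r)
            ok = disc > 0
            t = -b - np.sqrt(np.where(ok, disc, 0.0))
            ok &= (t > 1e-6) & (t < depth)
            if ok.any():
                pts = origin[None, :] + t[ok, None] * dirs[ok]
                normals = (pts - c) / r
                shade = 0.55 + 0.45 * np.clip(normals @ LIGHT_DIR, 0, 1)
                depth[ok] = t[ok]
                color[ok] = col * shade[:, None]
                owner[ok] = ch
        else:
            spec = ObjectSpec(body["shape"], tuple(body["size"]), (0, 0, 0.0),
                              1.0, -1) if body["shape"] != "box" else None
            parts = (spec.parts() if spec is not None
                     else [(np.zeros(3), np.asarray(body["size"], float))])
            Rb = quat_to_matrix(np.asarray(body["orientation"], float))
            centre = np.asarray(body["position"], float)
            for off, ext in parts:
                pc = centre + Rb @ off
                half = np.asarray(ext, float) / 2.0
                # slab test in the body frame
                o_l = (origin - pc) @ Rb
                d_l = dirs @ Rb
                with np.errstate(divide="ignore", invalid="ignore"):
                    inv = 1.0 / d_l
                t1 = (-half - o_l) * inv
                t2 = (half - o_l) * inv
                tmin = np.minimum(t1, t2).max(axis=1)
                tmax = np.maximum(t1, t2).min(axis=1)
                ok = (tmax > tmin) & (tmax > 1e-6) & (tmin < depth) & (tmin > 1e-6)
                if not ok.any():
                    continue
                tm = tmin[ok]
                pts_l = o_l[None, :] + tm[:, None] * d_l[ok]
                axis = np.argmax(np.abs(pts_l) / half[None, :], axis=1)
                sign = np.sign(pts_l[np.arange(len(axis)), axis])
                n_l = np.zeros((len(axis), 3))
                n_l[np.arange(len(axis)), axis] = sign
                normals = n_l @ Rb.T
                shade = 0.55 + 0.45 * np.clip(normals @ LIGHT_DIR, 0, 1)
                depth[ok] = tm
                color[ok] = col * shade[:, None]
                owner[ok] = ch

    img = np.clip(color, 0.0, 1.0).reshape(H, W, 3)
    return img, owner.reshape(H, W)


def image_to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


# --------------------------------------------------------------------------
# scripted motions
# --------------------------------------------------------------------------

def _script_pose(kind: str, p: dict, t: float,
                 duration: float, g: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form (position, orientation) for scripted bodies at time t."""
    if kind == "curtain":
        # descend, hold, retract; physically plausible constant-speed travel
        z_hi, z_lo = p["z_high"], p["z_low"]
        t1, t2, t3 = p["t_down"], p["t_hold_until"], p["t_up_until"]
        if t < t1:
            z = z_hi + (z_lo - z_hi) * (t / t1)
        elif t < t2:
            z = z_lo
        elif t < t3:
            z = z_lo + (z_hi - z_lo) * ((t - t2) / (t3 - t2))
        else:
            z = z_hi
        return np.array([p["x"], p["y"], z]), QUAT_ID.copy()
    if kind == "plank":
        # gravity-like quadratic fall about a hinge, clamped at the rest angle
        a0, a_rest, t_fall = p["angle0"], p["angle_rest"], p["t_fall"]
        frac = min(t / t_fall, 1.0) ** 2
        ang = max(a0 - (a0 - 0.0) * frac, a_rest)
        hinge = np.asarray(p["hinge"], float)
        L, thick = p["length"], p["thickness"]
        d = np.array([0.0, -math.cos(ang), math.sin(ang)])   # hinge -> far edge
        n = np.array([0.0, math.sin(ang), math.cos(ang)])    # plank top normal
        centre = hinge + d * (L / 2.0) + n * (thick / 2.0)
        quat = quat_from_axis_angle([1.0, 0.0, 0.0], -ang)
        return centre, quat
    if kind == "cover":
        # container falls from z0 and seats at z_rest
        z0, z_rest, t_land = p["z0"], p["z_rest"], p["t_land"]
        if t < t_land:
            frac = (t / t_land) ** 2
            z = z0 + (z_rest - z0) * frac
        else:
            z = z_rest
        return np.array([p["x"], p["y"], z]), QUAT_ID.copy()
    if kind == "ramp_roll":
        # accelerate down the slope (a = g sin(theta)), then roll on the floor
        p0 = np.asarray(p["top"], float)
        d_slope = np.asarray(p["slope_dir"], float)
        s_max = p["slope_len"]
        a = g * abs(d_slope[2])
        t_bottom = math.sqrt(2 * s_max / a) if a > 0 else float("inf")
        if t < t_bottom:
            s = 0.5 * a * t * t
            pos = p0 + d_slope * s
        else:
            v = a * t_bottom
            flat = d_slope.copy()
            flat[2] = 0.0
            flat /= max(np.linalg.norm(flat), 1e-9)
            pos = p0 + d_slope * s_max + flat * v * (t - t_bottom)
            pos[2] = p["radius"]
        return pos, QUAT_ID.copy()
    if kind == "polyline":
        pts = np.asarray(p["points"], float)
        times = np.asarray(p["times"], float)
        if t <= times[0]:
            return pts[0].copy(), QUAT_ID.copy()
        if t >= times[-1]:
            return pts[-1].copy(), QUAT_ID.copy()
        i = int(np.searchsorted(times, t, side="right")) - 1
        f = (t - times[i]) / (times[i + 1] - times[i])
        return pts[i] + f * (pts[i + 1] - pts[i]), QUAT_ID.copy()
    raise ValueError(f"unknown script kind {kind!r}")


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _half_height(spec: ObjectSpec) -> float:
    return spec.size[2] / 2.0 if spec.shape != "sphere" else spec.size[0] / 2.0


def _static_tops(objects, states) -> list[tuple[float, float, float, float, float, float]]:
    """World-frame AABBs (x0,x1,y0,y1,top,mass) of unrotated static parts."""
    boxes = []
    for (spec, _, beh), st in zip(objects, states):
        if beh.kind not in ("static",):
            continue
        if abs(st.orientation[0] - 1.0) > 1e-9:
            continue   # rotated statics (ramps) excluded from support queries
        for off, ext in (spec.parts() or []):
            c = st.position + off
            h = np.asarray(ext, float) / 2
            boxes.append((c[0] - h[0], c[0] + h[0], c[1] - h[1], c[1] + h[1],
                          c[2] + h[2], spec.mass))
        if spec.shape == "sphere":
            r = spec.size[0] / 2
            c = st.position
            boxes.append((c[0] - r, c[0] + r, c[1] - r, c[1] + r, c[2] + r, spec.mass))
    return boxes


def simulate_scene(spec: SceneSpec, n_steps: int = 3000, T: int = 15,
                   H: int = 64, W: int = 64, K: int | None = None) -> VideoRecord:
    """Advance the simplified physics core and render T uniformly spaced frames.

    Frames are sampled at steps linspace(0, n_steps, T) rounded to integers,
    including the first and last step.
    """
    if n_steps < T:
        raise ValueError("n_steps must be >= T")
    dt = spec.duration / n_steps
    g = spec.gravity

    states = [BodyState(s.position.copy(), s.velocity.copy(), s.orientation.copy())
              for _, s, _ in spec.objects]
    kinds = [b.kind for _, _, b in spec.objects]
    frame_steps = np.round(np.linspace(0, n_steps, T)).astype(int)

    # camera
    if isinstance(spec.camera, CameraTrack):
        cam = spec.camera
    elif spec.camera == "drifting":
        cam = drift_camera(spec.seed, T)
    else:
        cam = canonical_camera(T)

    statics = _static_tops(spec.objects, states)
    snapshots: list[list[tuple[np.ndarray, np.ndarray]]] = []
    max_speed = [float(np.linalg.norm(s.velocity)) for s in states]

    def capture():
        snapshots.append([(st.position.copy(), st.orientation.copy())
                          for st in states])

    for step in range(n_steps + 1):
        t_now = step * dt
        # scripted bodies are pure functions of time
        for i, (obj, _, beh) in enumerate(spec.objects):
            if beh.kind == "script":
                pos, quat = _script_pose(beh.params["script"], beh.params,
                                         t_now, spec.duration, g)
                states[i].position = pos
                states[i].orientation = quat
        if step in frame_steps:
            capture()
        if step == n_steps:
            break
        for i, (obj, _, beh) in enumerate(spec.objects):
            st = states[i]
            if kinds[i] == "rolling":
                st.position = st.position + st.velocity * dt
                _resolve_static_contacts(obj, st, statics)
            elif kinds[i] == "ballistic":
                acc = np.array([0.0, 0.0, -g])
                st.position = st.position + st.velocity * dt + 0.5 * acc * dt * dt
                st.velocity = st.velocity + acc * dt
                hh = _half_height(obj)
                support = _support_height(st.position, statics, obj)
                if st.velocity[2] < 0 and st.position[2] - hh <= support:
                    st.position[2] = support + hh
                    st.velocity[2] = 0.0
                    kinds[i] = "rolling" if np.linalg.norm(st.velocity[:2]) > 1e-9 \
                        else "resting"
            if np.any(~np.isfinite(st.position)):
                raise FloatingPointError("NaN/Inf in body state")
            sp = float(np.linalg.norm(st.velocity))
            max_speed[i] = max(max_speed[i], sp)

    frames = np.empty((T, H, W, 3), dtype=np.uint8)
    if K is None:
        K = max((o.object_id for o, _, _ in spec.objects), default=0) + 1
    labels = np.empty((T, H, W), dtype=np.uint8)
    states_per_frame = []
    for f, snap in enumerate(snapshots):
        bodies = []
        for (obj, _, beh), (pos, quat) in zip(spec.objects, snap):
            hidden = f in set(beh.params.get("hidden_frames", []))
            bodies.append({"shape": obj.shape, "size": obj.size, "color": obj.color,
                           "position": pos, "orientation": quat,
                           "channel": obj.object_id, "hidden": hidden})
        img, owner = render_frame(bodies, (cam.positions[f], cam.quats[f]),
                                  spec.floor_colors, H, W)
        frames[f] = image_to_uint8(img)
        labels[f] = owner.astype(np.uint8)
        states_per_frame.append([pos.copy() for pos, _ in snap])

    masks = labels_to_masks(labels, K)
    warnings = []
    for obj, _, _ in spec.objects:
        if masks[:, obj.object_id].sum() == 0:
            warnings.append(f"object {obj.object_id} never visible in any frame")
    meta = {"seed": spec.seed, "spec_hash": spec.hash(), "concept": None,
            "warnings": warnings,
            "positions": np.array(states_per_frame) if states_per_frame else None,
            "frame_times": (frame_steps * dt).tolist()}
    rec = VideoRecord(frames, masks, cam, meta)
    return rec


def _support_height(position: np.ndarray, statics, obj: ObjectSpec) -> float:
    x, y = position[0], position[1]
    support = 0.0
    for (x0, x1, y0, y1, top, _mass) in statics:
        if x0 <= x <= x1 and y0 <= y <= y1 and top <= position[2]:
            support = max(support, top)
    return support


def _resolve_static_contacts(obj: ObjectSpec, st: BodyState, statics) -> None:
    """Sphere vs. static AABB: reflect off heavy bodies, stop on light ones."""
    if obj.shape != "sphere":
        return
    r = obj.size[0] / 2
    c = st.position
    for (x0, x1, y0, y1, top, mass) in statics:
        if c[2] - r > top:
            continue
        closest = np.array([np.clip(c[0], x0, x1), np.clip(c[1], y0, y1)])
        d = c[:2] - closest
        dist = np.linalg.norm(d)
        if dist < r and dist > 1e-9:
            n = d / dist
            if mass >= HEAVY_MASS:
                vn = st.velocity[:2] @ n
                if vn < 0:
                    st.velocity[:2] = st.velocity[:2] - 2 * vn * n
                st.position[:2] = closest + n * (r + 1e-6)
            else:
                st.velocity[:] = 0.0
                st.position[:2] = closest + n * (r + 1e-6)


# --------------------------------------------------------------------------
# freeform scene sampling
# --------------------------------------------------------------------------

@dataclass
class SceneConfig:
    enabled_blocks: tuple[str, ...] = ("rolling", "ground_collision",
                                       "throw_collision", "occlusion_curtain",
                                       "stack", "covering", "containment", "ramp")
    n_blocks_range: tuple[int, int] = (2, 4)
    K: int = 8                       # mask channels (channel 0 reserved for the floor)
    compose_prob: float = 0.5
    region: float = 3.2              # half-extent of the active floor region
    max_retries: int = 40
    camera: str = "drifting"


# objects each block contributes
_BLOCK_COST = {"rolling": 1, "ground_collision": 2, "throw_collision": 1,
               "occlusion_curtain": 1, "stack": 1, "covering": 2,
               "containment": 2, "ramp": 2}


def _rand_color(rng):
    return tuple(rng.uniform(0.08, 0.95, 3).round(4))


def sample_freeform_scene(rng_seed: int, config: SceneConfig | None = None) -> SceneSpec:
    """Compose 2-4 scene building blocks into one freeform training scene.

    Blocks compose by advertising and/or consuming floor locations of
    interest (a rolling sphere can target a stack's centre, a cover can drop
    on a previously placed object); with probability 1 - compose_prob a block
    ignores existing locations and inhabits the scene independently.
    """
    config = config or SceneConfig()
    rng = np.random.default_rng(rng_seed)
    for attempt in range(config.max_retries):
        try:
            spec = _try_sample(rng, config, rng_seed)
            return spec
        except GenerationError:
            continue
    raise GenerationError(f"could not compose a scene after {config.max_retries} tries")


def _try_sample(rng, config: SceneConfig, seed: int) -> SceneSpec:
    capacity = config.K - 1
    n_blocks = int(rng.integers(config.n_blocks_range[0],
                                config.n_blocks_range[1] + 1))
    chosen: list[str] = []
    budget = capacity
    candidates = list(config.enabled_blocks)
    for _ in range(n_blocks):
        affordable = [b for b in candidates if _BLOCK_COST[b] <= budget]
        if not affordable:
            break
        b = str(rng.choice(affordable))
        chosen.append(b)
        budget -= _BLOCK_COST[b]
    if len(chosen) < config.n_blocks_range[0]:
        raise GenerationError("insufficient mask channels for requested blocks")

    objects: list[tuple[ObjectSpec, BodyState, Behavior]] = []
    locations: list[np.ndarray] = []       # advertised locations of interest
    occupied: list[tuple[np.ndarray, float]] = []
    next_id = 1
    R = config.region

    def place(radius, tries=25):
        for _ in range(tries):
            p = rng.uniform(-R + radius, R - radius, 2)
            if all(np.linalg.norm(p - q) > radius + r0 + 0.15 for q, r0 in occupied):
                return p
        raise GenerationError("no free space")

    def maybe_target(fallback_radius=0.4):
        if locations and rng.random() < config.compose_prob:
            return locations[int(rng.integers(len(locations)))].copy(), True
        return np.append(place(fallback_radius), 0.0), False

    blocks_meta = []
    for name in chosen:
        if name == "rolling":
            r = rng.uniform(0.28, 0.45)
            target, composed = maybe_target(r)
            start_xy = place(r)
            d = target[:2] - start_xy
            dist = max(np.linalg.norm(d), 1e-6)
            speed = rng.uniform(1.8, 3.2)
            vel = np.append(d / dist * speed, 0.0)
            sp = ObjectSpec("sphere", (2 * r,) * 3, _rand_color(rng),
                            MASS_ROLLED, next_id)
            objects.append((sp, BodyState(np.append(start_xy, r), vel),
                            Behavior("rolling")))
            occupied.append((start_xy, r))
            locations += [np.append(start_xy, 0.0), target]
            blocks_meta.append({"block": name, "composed": composed,
                                "target": target.tolist()})
            next_id += 1
        elif name == "ground_collision":
            r = rng.uniform(0.28, 0.4)
            box_xy = place(0.5)
            ext = tuple(rng.uniform(0.5, 0.9, 3).round(3))
            box = ObjectSpec("box", ext, _rand_color(rng), MASS_ROLLED, next_id)
            objects.append((box, BodyState(np.append(box_xy, ext[2] / 2),
                                           np.zeros(3)), Behavior("static")))
            occupied.append((box_xy, max(ext) / 2))
            next_id += 1
            start_xy = place(r)
            d = box_xy - start_xy
            dist = max(np.linalg.norm(d), 1e-6)
            vel = np.append(d / dist * rng.uniform(2.0, 3.4), 0.0)
            sph = ObjectSpec("sphere", (2 * r,) * 3, _rand_color(rng),
                             MASS_ROLLED, next_id)
            objects.append((sph, BodyState(np.append(start_xy, r), vel),
                            Behavior("rolling")))
            occupied.append((start_xy, r))
            locations.append(np.append(box_xy, 0.0))
            blocks_meta.append({"block": name})
            next_id += 1
        elif name == "throw_collision":
            target, composed = maybe_target()
            r = rng.uniform(0.25, 0.4)
            launch = np.array([target[0] + rng.uniform(-1.5, 1.5),
                               target[1] + rng.uniform(-1.5, 1.5),
                               rng.uniform(2.2, 3.2)])
            t_hit = rng.uniform(0.5, 0.9)
            vel = (target + np.array([0, 0, r]) - launch) / t_hit
            vel[2] += 0.5 * G_DEFAULT * t_hit
            sp = ObjectSpec("sphere", (2 * r,) * 3, _rand_color(rng),
                            MASS_DROPPED, next_id)
            objects.append((sp, BodyState(launch, vel), Behavior("ballistic")))
            blocks_meta.append({"block": name, "composed": composed})
            next_id += 1
        elif name == "occlusion_curtain":
            w = rng.uniform(1.6, 2.6)
            x = rng.uniform(-R / 2, R / 2)
            y = rng.uniform(-1.2, -0.4)
            h = rng.uniform(1.6, 2.2)
            sp = ObjectSpec("curtain", (w, 0.1, h), _rand_color(rng),
                            MASS_ROLLED, next_id)
            beh = Behavior("script", {
                "script": "curtain", "x": x, "y": y,
                "z_high": h / 2 + 2.6, "z_low": h / 2,
                "t_down": 0.6, "t_hold_until": 1.1, "t_up_until": 1.8})
            objects.append((sp, BodyState([x, y, h / 2 + 2.6], np.zeros(3)), beh))
            blocks_meta.append({"block": name})
            next_id += 1
        elif name == "stack":
            xy = place(0.6)
            n_tiers = int(rng.integers(2, 4))
            base = rng.uniform(0.55, 0.8)
            # one object id for the whole stack: a static composite of boxes
            color = _rand_color(rng)
            z = 0.0
            for tier in range(n_tiers):
                s = base * (1.0 - 0.22 * tier)
                h = float(rng.uniform(0.3, 0.45))
                sp = ObjectSpec("box", (s, s, h), color, MASS_ROLLED, next_id)
                objects.append((sp, BodyState(np.append(xy, z + h / 2),
                                              np.zeros(3)), Behavior("static")))
                z += h
            occupied.append((xy, base / 2))
            locations.append(np.append(xy, 0.0))
            blocks_meta.append({"block": name, "tiers": n_tiers,
                                "location": xy.tolist()})
            next_id += 1
        elif name == "covering":
            target, composed = maybe_target()
            ext = rng.uniform(0.35, 0.55)
            small = ObjectSpec("box", (ext, ext, ext), _rand_color(rng),
                               MASS_ROLLED, next_id)
            objects.append((small, BodyState(np.append(target[:2], ext / 2),
                                             np.zeros(3)), Behavior("static")))
            occupied.append((target[:2].copy(), ext / 2))
            next_id += 1
            cw = ext * rng.uniform(1.8, 2.4)
            ch = ext * rng.uniform(1.5, 2.0)
            cont = ObjectSpec("closed_container", (cw, cw, ch),
                              _rand_color(rng),
                              float(rng.choice(MASS_CONTAINER)), next_id)
            beh = Behavior("script", {
                "script": "cover", "x": float(target[0]), "y": float(target[1]),
                "z0": ch / 2 + 2.8, "z_rest": ch / 2, "t_land": 0.8})
            objects.append((cont, BodyState([target[0], target[1], ch / 2 + 2.8],
                                            np.zeros(3)), beh))
            blocks_meta.append({"block": name, "composed": composed})
            next_id += 1
        elif name == "containment":
            xy = place(0.7)
            cw = rng.uniform(1.0, 1.5)
            chh = rng.uniform(0.9, 1.3)
            cont = ObjectSpec("open_container", (cw, cw, chh), _rand_color(rng),
                              float(rng.choice(MASS_CONTAINER)), next_id)
            objects.append((cont, BodyState(np.append(xy, chh / 2), np.zeros(3)),
                            Behavior("static")))
            occupied.append((xy, cw / 2))
            next_id += 1
            ext = cw * rng.uniform(0.28, 0.4)
            block = ObjectSpec("box", (ext, ext, ext), _rand_color(rng),
                               MASS_DROPPED, next_id)
            objects.append((block, BodyState(np.append(xy, chh + rng.uniform(1.2, 2.0)),
                                             np.zeros(3)), Behavior("ballistic")))
            locations.append(np.append(xy, 0.0))
            blocks_meta.append({"block": name})
            next_id += 1
        elif name == "ramp":
            xy = place(1.0)
            length, height = rng.uniform(1.6, 2.2), rng.uniform(0.7, 1.1)
            ang = math.atan2(height, length)
            ramp = ObjectSpec("ramp", (0.9, math.hypot(length, height), 0.12),
                              _rand_color(rng), MASS_ROLLED, next_id)
            quat = quat_from_axis_angle([1, 0, 0], ang)
            centre = np.array([xy[0], xy[1], height / 2])
            objects.append((ramp, BodyState(centre, np.zeros(3), quat),
                            Behavior("static")))
            occupied.append((xy, length / 2))
            next_id += 1
            r = rng.uniform(0.22, 0.3)
            top = np.array([xy[0], xy[1] - length / 2 + 0.1, height + r])
            slope = np.array([0.0, length, -height])
            slope = slope / np.linalg.norm(slope)
            sph = ObjectSpec("sphere", (2 * r,) * 3, _rand_color(rng),
                             MASS_ROLLED, next_id)
            beh = Behavior("script", {"script": "ramp_roll", "top": top.tolist(),
                                      "slope_dir": slope.tolist(),
                                      "slope_len": math.hypot(length, height),
                                      "radius": r})
            objects.append((sph, BodyState(top, np.zeros(3)), beh))
            locations.append(np.append(xy, 0.0))
            blocks_meta.append({"block": name})
            next_id += 1
        else:
            raise ValueError(f"unknown block {name!r}")

    floor = (_rand_color(rng), _rand_color(rng))
    return SceneSpec(objects, floor, config.camera, seed, blocks=blocks_meta)
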