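"""Probe tuples for five physical concepts via matched-frame splicing.

A probe tuple holds two physically possible and two physically impossible
videos. The impossible videos are built by recombining start segments, a
shared common frame and end segments of the possible pair (start A + common
+ end B and vice versa), so that

* frame match — the multiset of (frame, mask) images over both impossible
  videos equals that over both possible videos, pixel-exactly; and
* pair match — every ordered adjacent frame pair occurring in an impossible
  video also occurs in a possible video.

These two properties guarantee that no single image and no single frame
transition can explain a violation-of-expectation effect; only longer-range
temporal structure can. `verify_probe_tuple` checks both properties by brute
force and is used as an independent gate on every generated tuple.

The continuity probes deviate from the segment-swap template: they are built
by rendering the same rolling-ball scene with the ball flagged invisible on
complementary frame intervals, relying on frames of full occlusion being
pixel-identical to frames of the matched empty scene. The verifier applies
unchanged.

All probe cameras are stationary (per concept, shared by the four videos of
a tuple), so the occlusions that hide each splice are stable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .world import (
    Behavior, BodyState, CameraTrack, GenerationError, ObjectSpec, SceneSpec,
    VideoRecord, canonical_camera, look_at_quat, simulate_scene,
)

CONCEPTS = ("continuity", "persistence", "unchangeableness",
            "solidity", "directional_inertia")


@dataclass
class ProbeProfile:
    """Rendering scale for probe generation (image size, channels, frames)."""
    H: int = 64
    W: int = 64
    K: int = 8
    T: int = 15
    n_steps: int = 700
    max_retries: int = 12


PAPER_PROFILE = ProbeProfile()
DESK_PROFILE = ProbeProfile(H=32, W=32, K=4)


@dataclass
class SegmentSet:
    """Start/end segments around one shared frame, as (frames, masks) arrays."""
    start_A: tuple[np.ndarray, np.ndarray]
    start_B: tuple[np.ndarray, np.ndarray]
    common: tuple[np.ndarray, np.ndarray]     # single frame
    end_A: tuple[np.ndarray, np.ndarray]
    end_B: tuple[np.ndarray, np.ndarray]
    camera: CameraTrack = None

    def validate(self) -> None:
        if self.start_A[0].shape != self.start_B[0].shape:
            raise ValueError("start segment length/shape mismatch")
        if self.end_A[0].shape != self.end_B[0].shape:
            raise ValueError("end segment length/shape mismatch")


@dataclass
class ProbeTuple:
    concept: str
    possible: list[VideoRecord]
    impossible: list[VideoRecord]
    violation_onset: tuple[int, int]          # per impossible video
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def all_videos(self):
        return list(self.possible) + list(self.impossible)

    def validate(self) -> None:
        assert len(self.possible) == 2 and len(self.impossible) == 2
        shapes = {v.frames.shape for v in self.all_videos()}
        assert len(shapes) == 1, "all four videos must share T, H, W"
        cams = {v.camera.encode().tobytes() for v in self.all_videos()}
        assert len(cams) == 1, "cameras must be identical across the tuple"
        cam = self.possible[0].camera
        assert np.ptp(cam.positions, axis=0).max() == 0, "probe camera must be stationary"
        T = self.possible[0].T
        for onset in self.violation_onset:
            assert 1 <= onset <= T - 1


def splice(segments: SegmentSet, concept: str = "generic",
           seed: int = 0) -> ProbeTuple:
    """Assemble possible (A+c+A, B+c+B) and impossible (A+c+B, B+c+A) videos."""
    segments.validate()
    c_f, c_m = segments.common
    onset = len(segments.start_A[0]) + 1

    def build(start, end, role):
        frames = np.concatenate([start[0], c_f[None], end[0]])
        masks = np.concatenate([start[1], c_m[None], end[1]])
        return VideoRecord(frames, masks, segments.camera,
                           {"role": role, "concept": concept})

    possible = [build(segments.start_A, segments.end_A, "possible_A"),
                build(segments.start_B, segments.end_B, "possible_B")]
    impossible = [build(segments.start_A, segments.end_B, "impossible_AB"),
                  build(segments.start_B, segments.end_A, "impossible_BA")]
    return ProbeTuple(concept, possible, impossible, (onset, onset), seed)


# --------------------------------------------------------------------------
# verifier
# --------------------------------------------------------------------------

@dataclass
class VerifyReport:
    frame_match: bool
    pair_match: bool
    frame_fail_index: tuple[int, int] | None = None   # (impossible video, frame)
    pair_fail_index: tuple[int, int] | None = None

    @property
    def ok(self) -> bool:
        return self.frame_match and self.pair_match


def _frame_keys(video: VideoRecord) -> list[bytes]:
    return [video.frames[t].tobytes() + video.masks[t].tobytes()
            for t in range(video.T)]


def verify_probe_tuple(tup: ProbeTuple) -> VerifyReport:
    """Brute-force check of the frame-multiset and adjacent-pair guarantees."""
    poss_keys = [_frame_keys(v) for v in tup.possible]
    imp_keys = [_frame_keys(v) for v in tup.impossible]

    poss_counter = Counter(k for ks in poss_keys for k in ks)
    imp_counter = Counter(k for ks in imp_keys for k in ks)
    frame_match = poss_counter == imp_counter
    frame_fail = None
    if not frame_match:
        for vi, ks in enumerate(imp_keys):
            running = Counter()
            for t, k in enumerate(ks):
                running[k] += 1
                if running[k] > poss_counter.get(k, 0):
                    frame_fail = (vi, t)
                    break
            if frame_fail:
                break
        if frame_fail is None:
            frame_fail = (0, 0)

    poss_pairs = {(ks[t], ks[t + 1]) for ks in poss_keys for t in range(len(ks) - 1)}
    pair_match, pair_fail = True, None
    for vi, ks in enumerate(imp_keys):
        for t in range(len(ks) - 1):
            if (ks[t], ks[t + 1]) not in poss_pairs:
                pair_match, pair_fail = False, (vi, t)
                break
        if not pair_match:
            break
    return VerifyReport(frame_match, pair_match, frame_fail, pair_fail)


# --------------------------------------------------------------------------
# shared helpers for the concept makers
# --------------------------------------------------------------------------

def _static_camera(T: int, position, target) -> CameraTrack:
    pos = np.asarray(position, float)
    q = look_at_quat(pos, np.asarray(target, float))
    return CameraTrack(np.tile(pos, (T, 1)), np.tile(q, (T, 1)))


def _rand_color(rng) -> tuple[float, float, float]:
    return tuple(rng.uniform(0.1, 0.95, 3).round(4))


def _simulate(spec: SceneSpec, prof: ProbeProfile) -> VideoRecord:
    return simulate_scene(spec, n_steps=prof.n_steps, T=prof.T,
                          H=prof.H, W=prof.W, K=prof.K)


def _segments_from(vid_a: VideoRecord, vid_b: VideoRecord,
                   t_c: int) -> SegmentSet:
    if not (np.array_equal(vid_a.frames[t_c], vid_b.frames[t_c])
            and np.array_equal(vid_a.masks[t_c], vid_b.masks[t_c])):
        raise GenerationError("common frame is not pixel-identical")
    return SegmentSet(
        start_A=(vid_a.frames[:t_c], vid_a.masks[:t_c]),
        start_B=(vid_b.frames[:t_c], vid_b.masks[:t_c]),
        common=(vid_a.frames[t_c], vid_a.masks[t_c]),
        end_A=(vid_a.frames[t_c + 1:], vid_a.masks[t_c + 1:]),
        end_B=(vid_b.frames[t_c + 1:], vid_b.masks[t_c + 1:]),
        camera=vid_a.camera,
    )


def _with_retries(builder, rng_seed: int, prof: ProbeProfile) -> ProbeTuple:
    seq = np.random.SeedSequence(rng_seed)
    last: Exception | None = None
    for child in seq.spawn(prof.max_retries):
        rng = np.random.default_rng(child)
        try:
            tup = builder(rng, prof)
        except GenerationError as err:
            last = err
            continue
        tup.seed = rng_seed
        report = verify_probe_tuple(tup)
        if not report.ok:
            last = GenerationError(f"verifier rejected tuple: {report}")
            continue
        tup.validate()
        return tup
    raise GenerationError(f"probe generation failed after retries: {last}")


# --------------------------------------------------------------------------
# continuity: a ball rolls behind two pillars
# --------------------------------------------------------------------------

def make_continuity_probe(rng_seed: int,
                          profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    """Ball rolls behind two pillars; impossible variants never show it between them.

    Built by visibility masking rather than segment swap: possible-1 shows the
    full roll, possible-2 the same scene with no ball; impossible-1 hides the
    ball exactly while it would be visible between the pillars, impossible-2
    shows it only there. Pillar width equals the ball's diameter, so a fully
    occluded ball yields frames pixel-identical to the empty scene — which is
    what makes the frame/pair-matching guarantees hold and is checked per
    tuple.
    """

    def build(rng, prof: ProbeProfile) -> ProbeTuple:
        T = prof.T
        r = rng.uniform(0.38, 0.5)
        xp = rng.uniform(1.0, 1.4)
        y_ball = rng.uniform(1.1, 1.5)
        t1, t2 = 4, 10                      # full-occlusion alignment frames
        stride = 2 * xp / (t2 - t1)
        x0 = -xp - t1 * stride
        duration = 2.0
        frame_dt = duration / (T - 1)
        speed = stride / frame_dt

        pillar_h = rng.uniform(1.6, 2.1)
        pcol = _rand_color(rng)
        pillars = [
            (ObjectSpec("box", (2 * r, 0.3, pillar_h), pcol, 10.0, 1),
             BodyState([-xp, 0.0, pillar_h / 2], np.zeros(3)), Behavior("static")),
            (ObjectSpec("box", (2 * r, 0.3, pillar_h), pcol, 10.0, 2),
             BodyState([xp, 0.0, pillar_h / 2], np.zeros(3)), Behavior("static")),
        ]
        ball = (ObjectSpec("sphere", (2 * r,) * 3, _rand_color(rng), 10.0, 3),
                BodyState([x0, y_ball, r], [speed, 0.0, 0.0]),
                Behavior("rolling"))
        floor = (_rand_color(rng), _rand_color(rng))
        cam = canonical_camera(T)

        spec_full = SceneSpec(pillars + [ball], floor, cam, 0)
        spec_empty = SceneSpec(list(pillars), floor, cam, 0)
        vid_full = _simulate(spec_full, prof)
        vid_empty = _simulate(spec_empty, prof)

        # full occlusion at the alignment frames must be pixel-exact
        for t in (t1, t2):
            if not (np.array_equal(vid_full.frames[t], vid_empty.frames[t])
                    and np.array_equal(vid_full.masks[t], vid_empty.masks[t])):
                raise GenerationError("ball not fully occluded at alignment frame")

        gap = list(range(t1 + 1, t2))        # frames where the ball is between pillars
        outside = [t for t in range(T) if t not in gap]

        def hidden_variant(hidden_frames, role):
            objs = pillars + [(ball[0], ball[1],
                               Behavior("rolling", {"hidden_frames": hidden_frames}))]
            sp = SceneSpec(objs, floor, cam, 0)
            v = _simulate(sp, prof)
            v.meta["role"] = role
            v.meta["concept"] = "continuity"
            return v

        imp_never_between = hidden_variant(gap, "impossible_never_between")
        imp_only_between = hidden_variant(outside, "impossible_only_between")
        vid_full.meta.update(role="possible_ball", concept="continuity",
                             scene=spec_full.to_dict())
        vid_empty.meta.update(role="possible_empty", concept="continuity",
                              scene=spec_empty.to_dict())

        onset = t1 + 1                       # first frame the ball should reappear
        return ProbeTuple("continuity", [vid_full, vid_empty],
                          [imp_never_between, imp_only_between],
                          (onset, onset),
                          meta={"possible_specs": [spec_full.to_dict(),
                                                   spec_empty.to_dict()],
                                "occlusion_frames": [t1, t2]})

    return _with_retries(build, rng_seed, profile)


# --------------------------------------------------------------------------
# directional inertia: reflection off a heavy block
# --------------------------------------------------------------------------

def make_inertia_probe(rng_seed: int,
                       profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    """Ball bounces off a heavy block; impossible variants retrace the incoming path.

    Possible A runs start -> contact -> mirror-reflected end; possible B is the
    exact time reversal. Swapping ends at the contact frame sends the ball back
    toward where it came from, violating directional inertia.
    """

    def build(rng, prof: ProbeProfile) -> ProbeTuple:
        T = prof.T
        duration = 2.0
        r = rng.uniform(0.3, 0.42)
        half = np.array([rng.uniform(0.7, 1.0), rng.uniform(0.35, 0.5),
                         rng.uniform(0.5, 0.75)])
        block_c = np.array([rng.uniform(-0.4, 0.4), rng.uniform(0.6, 1.2), half[2]])
        theta = rng.uniform(math.radians(25), math.radians(65))
        sgn = rng.choice([-1.0, 1.0])
        # contact on the front (-y) face, normal (0,-1,0)
        cx = block_c[0] + sgn * rng.uniform(-0.3, 0.3) * half[0]
        contact = np.array([cx, block_c[1] - half[1] - r, r])
        d_in = np.array([sgn * math.sin(theta), math.cos(theta), 0.0])
        d_out = d_in - 2 * d_in[1] * np.array([0.0, 1.0, 0.0])   # mirror about the normal
        seg = rng.uniform(2.2, 3.0)
        p0 = contact - d_in * seg
        p1 = contact + d_out * seg
        t_c = (T - 1) // 2
        t_mid = t_c / (T - 1) * duration

        block = (ObjectSpec("box", tuple(2 * half), _rand_color(rng), 40.0, 1),
                 BodyState(block_c, np.zeros(3)), Behavior("static"))
        floor = (_rand_color(rng), _rand_color(rng))
        cam = canonical_camera(T)
        bcol = _rand_color(rng)

        def scene(points):
            ball = (ObjectSpec("sphere", (2 * r,) * 3, bcol, 10.0, 2),
                    BodyState(points[0], np.zeros(3)),
                    Behavior("script", {"script": "polyline",
                                        "points": [p.tolist() for p in points],
                                        "times": [0.0, t_mid, duration]}))
            return SceneSpec([block, ball], floor, cam, 0)

        spec_a = scene([p0, contact, p1])
        spec_b = scene([p1, contact, p0])
        vid_a, vid_b = _simulate(spec_a, prof), _simulate(spec_b, prof)
        if 3 in vid_a.masks[t_c].sum(axis=(1, 2)).nonzero()[0]:
            raise GenerationError("unexpected channel")
        segs = _segments_from(vid_a, vid_b, t_c)
        tup = splice(segs, "directional_inertia")
        tup.meta = {"possible_specs": [spec_a.to_dict(), spec_b.to_dict()],
                    "contact_frame": t_c, "incidence_deg": math.degrees(theta)}
        for v, sp in zip(tup.possible, (spec_a, spec_b)):
            v.meta["scene"] = sp.to_dict()
        return tup

    return _with_retries(build, rng_seed, profile)


# --------------------------------------------------------------------------
# unchangeableness: a screen hides a lineup that must not change
# --------------------------------------------------------------------------

def make_unchangeableness_probe(rng_seed: int,
                                profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    """Static object lineup, one full-width screen lowers and rises.

    Scene B swaps the objects' positions; splicing at a fully occluded frame
    makes the swap happen behind the screen, implying a change of position,
    colour or shape while hidden.
    """

    def build(rng, prof: ProbeProfile) -> ProbeTuple:
        T = prof.T
        n_obj = 2 if prof.K <= 4 else int(rng.integers(2, 4))
        slots = np.linspace(-1.4, 1.4, n_obj) + rng.uniform(-0.15, 0.15, n_obj)
        y_obj = 0.6

        objs_a = []
        for i in range(n_obj):
            shape = str(rng.choice(["box", "sphere"]))
            if shape == "sphere":
                d = rng.uniform(0.5, 0.8)
                size = (d, d, d)
            else:
                size = tuple(rng.uniform(0.45, 0.9, 3).round(3))
            spec = ObjectSpec(shape, size, _rand_color(rng), 10.0, i + 1)
            z = size[2] / 2 if shape == "box" else size[0] / 2
            objs_a.append((spec, np.array([slots[i], y_obj, z])))

        perm = np.roll(np.arange(n_obj), 1)   # cyclic swap of positions
        screen_h = 1.7
        screen = (ObjectSpec("curtain", (4.4, 0.12, screen_h),
                             _rand_color(rng), 10.0, n_obj + 1),
                  BodyState([0.0, -0.6, screen_h / 2 + 2.8], np.zeros(3)),
                  Behavior("script", {
                      "script": "curtain", "x": 0.0, "y": -0.6,
                      "z_high": screen_h / 2 + 2.8, "z_low": screen_h / 2,
                      "t_down": 0.62, "t_hold_until": 1.15, "t_up_until": 1.9}))
        floor = (_rand_color(rng), _rand_color(rng))
        cam = canonical_camera(T)

        def scene(order):
            objects = [(objs_a[i][0], BodyState(
                np.array([objs_a[j][1][0], y_obj, objs_a[i][1][2]]), np.zeros(3)),
                Behavior("static")) for i, j in zip(range(n_obj), order)]
            return SceneSpec(objects + [screen], floor, cam, 0)

        spec_a = scene(np.arange(n_obj))
        spec_b = scene(perm)
        vid_a, vid_b = _simulate(spec_a, prof), _simulate(spec_b, prof)
        t_c = 7                               # screen fully lowered
        segs = _segments_from(vid_a, vid_b, t_c)
        tup = splice(segs, "unchangeableness")
        tup.meta = {"possible_specs": [spec_a.to_dict(), spec_b.to_dict()],
                    "occluded_frame": t_c}
        for v, sp in zip(tup.possible, (spec_a, spec_b)):
            v.meta["scene"] = sp.to_dict()
        return tup

    return _with_retries(build, rng_seed, profile)


# --------------------------------------------------------------------------
# solidity: a block drops into a container seen from above its rim
# --------------------------------------------------------------------------

def make_solidity_probe(rng_seed: int,
                        profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    """Blocks of two heights drop into an open container.

    The camera views inside the top of the container but not the bottom. The
    tall block comes to rest with its top visible through the opening; the
    short one sinks out of sight. While both are falling with bottoms hidden
    behind the front wall, only their (identical) tops are visible — the
    common frame. Swapped ends give a block that "fell through" despite its
    height, and one that stays visible when it should have fallen further.
    """

    def build(rng, prof: ProbeProfile) -> ProbeTuple:
        T = prof.T
        duration = 2.0
        cw, chh = 1.6, 2.0
        a = rng.uniform(0.7, 0.9)             # block cross-section
        h_tall = rng.uniform(0.95, 1.15)
        h_short = rng.uniform(0.4, 0.5)
        xy = rng.uniform(-0.08, 0.08, 2)
        bcol = _rand_color(rng)
        ccol = _rand_color(rng)

        t_c = 4
        t_time = t_c / (T - 1) * duration
        z_top_common = rng.uniform(1.42, 1.55)          # inside the hidden band
        z0_top = z_top_common + 0.5 * 9.8 * t_time ** 2

        cam = _static_camera(T, (0.0, -3.5, 5.5), (0.0, 0.0, 0.5))
        floor = (_rand_color(rng), _rand_color(rng))
        container = (ObjectSpec("open_container", (cw, cw, chh), ccol, 4.0, 1),
                     BodyState([0.0, 0.0, chh / 2], np.zeros(3)),
                     Behavior("static"))

        def scene(h_block):
            blk = (ObjectSpec("box", (a, a, h_block), bcol, 40.0, 2),
                   BodyState([xy[0], xy[1], z0_top - h_block / 2], np.zeros(3)),
                   Behavior("ballistic"))
            return SceneSpec([container, blk], floor, cam, 0)

        spec_tall, spec_short = scene(h_tall), scene(h_short)
        vid_tall, vid_short = _simulate(spec_tall, prof), _simulate(spec_short, prof)
        # the tall block must stay visible at rest, the short one vanish
        if vid_tall.masks[-1, 2].sum() == 0:
            raise GenerationError("tall block invisible at rest")
        if vid_short.masks[-1, 2].sum() != 0:
            raise GenerationError("short block visible at rest")
        segs = _segments_from(vid_tall, vid_short, t_c)
        tup = splice(segs, "solidity")
        tup.meta = {"possible_specs": [spec_tall.to_dict(), spec_short.to_dict()],
                    "common_frame": t_c}
        for v, sp in zip(tup.possible, (spec_tall, spec_short)):
            v.meta["scene"] = sp.to_dict()
        return tup

    return _with_retries(build, rng_seed, profile)


# --------------------------------------------------------------------------
# object persistence: a plank falls onto an object (or onto nothing)
# --------------------------------------------------------------------------

def make_persistence_probe(rng_seed: int,
                           profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    """A rigid plank overturns onto an object and ends propped; or falls flat.

    Scene A contains a box under the plank's sweep: the plank occludes it
    during the fall and comes to rest propped on it. Scene B is the same
    empty-floor scene falling flat. The common frame is taken during the fall
    once the object is fully occluded. Mismatched ends yield a plank that
    ends flat despite the object (it ceased to persist) and one that ends
    propped on an object that was never there.
    """

    def build(rng, prof: ProbeProfile) -> ProbeTuple:
        T = prof.T
        duration = 2.0
        L, thick = 3.0, 0.12
        width = rng.uniform(2.2, 2.8)
        hinge_y = 1.5
        h_o = rng.uniform(0.75, 0.95)
        obj_y = rng.uniform(0.1, 0.3)
        obj_sx = rng.uniform(0.55, 0.8)
        angle0 = 1.35
        t_fall = 1.1
        alpha_rest = math.atan2(h_o, hinge_y - (obj_y + obj_sx / 2))
        t_c = 5
        t5 = t_c / (T - 1) * duration
        alpha_at_tc = angle0 * (1 - (t5 / t_fall) ** 2)
        if not (alpha_rest + 0.01 < alpha_at_tc < alpha_rest + 0.25):
            raise GenerationError("rest angle incompatible with splice frame")

        cam = _static_camera(T, (0.0, -2.0, 8.5), (0.0, 0.4, 0.0))
        floor = (_rand_color(rng), _rand_color(rng))
        pcol = _rand_color(rng)

        def plank(rest):
            spec = ObjectSpec("curtain", (width, L, thick), pcol, 10.0, 1)
            beh = Behavior("script", {
                "script": "plank", "hinge": [0.0, hinge_y, 0.0],
                "length": L, "thickness": thick,
                "angle0": angle0, "angle_rest": rest, "t_fall": t_fall})
            return (spec, BodyState([0.0, hinge_y, L / 2], np.zeros(3),
                                    ), beh)

        obj = (ObjectSpec("box", (obj_sx, obj_sx, h_o), _rand_color(rng),
                          10.0, 2),
               BodyState([0.0, obj_y, h_o / 2], np.zeros(3)), Behavior("static"))
        spec_a = SceneSpec([plank(alpha_rest), obj], floor, cam, 0)
        spec_b = SceneSpec([plank(0.0)], floor, cam, 0)
        vid_a, vid_b = _simulate(spec_a, prof), _simulate(spec_b, prof)
        # the object must be visible early and fully occluded from the common frame on
        if vid_a.masks[0, 2].sum() == 0:
            raise GenerationError("object not visible at video start")
        if vid_a.masks[t_c:, 2].sum() != 0:
            raise GenerationError("object visible after occlusion onset")
        segs = _segments_from(vid_a, vid_b, t_c)
        tup = splice(segs, "persistence")
        tup.meta = {"possible_specs": [spec_a.to_dict(), spec_b.to_dict()],
                    "common_frame": t_c, "prop_angle": alpha_rest}
        for v, sp in zip(tup.possible, (spec_a, spec_b)):
            v.meta["scene"] = sp.to_dict()
        return tup

    return _with_retries(build, rng_seed, profile)


_MAKERS = {
    "continuity": make_continuity_probe,
    "persistence": make_persistence_probe,
    "unchangeableness": make_unchangeableness_probe,
    "solidity": make_solidity_probe,
    "directional_inertia": make_inertia_probe,
}


def make_probe(concept: str, rng_seed: int,
               profile: ProbeProfile = PAPER_PROFILE) -> ProbeTuple:
    if concept not in _MAKERS:
        raise ValueError(f"unknown concept {concept!r}; choose from {CONCEPTS}")
    return _MAKERS[concept](rng_seed, profile)


def generate_probe_tuples(concept: str, n_tuples: int, seed: int,
                          profile: ProbeProfile = PAPER_PROFILE) -> list[ProbeTuple]:
    """Generate n verified tuples for one concept (seeded, deterministic)."""
    seq = np.random.SeedSequence(seed)
    out = []
    for child in seq.generate_state(n_tuples).astype(np.int64):
        out.append(make_probe(concept, int(child) & 0x7FFFFFFF, profile))
    return out


def generate_probe_set(concept: str, n_tuples: int, seed: int, out_dir,
                       profile: ProbeProfile = PAPER_PROFILE):
    """Generate, verify and serialize a probe dataset; returns its manifest."""
    from .data import write_probe_dataset
    tuples = generate_probe_tuples(concept, n_tuples, seed, profile)
    return write_probe_dataset(out_dir, tuples, concept=concept, seed=seed)
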