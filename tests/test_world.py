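"""Simulator and renderer: invariants, closed forms, determinism."""

from pathlib import Path

import numpy as np
import pytest

from physvoe import world as w

GOLDEN = Path(__file__).parent / "data" / "golden_red_box_16.csv"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(shape="pyramid", size=(1, 1, 1), color=(0, 0, 0), mass=1, object_id=1),
    dict(shape="box", size=(1, -1, 1), color=(0, 0, 0), mass=1, object_id=1),
    dict(shape="box", size=(1, 1, 1), color=(0, 0, 1.5), mass=1, object_id=1),
    dict(shape="box", size=(1, 1, 1), color=(0, 0, 1), mass=0, object_id=1),
])
def test_object_spec_invariants(bad):
    with pytest.raises(ValueError):
        w.ObjectSpec(**bad)


def test_composites_decompose_into_boxes():
    arch = w.ObjectSpec("arch", (2, 0.5, 1.5), (0.5, 0.5, 0.5), 60.0, 1)
    assert len(arch.parts()) == 3
    open_c = w.ObjectSpec("open_container", (1, 1, 1), (0.5,) * 3, 4.0, 2)
    closed_c = w.ObjectSpec("closed_container", (1, 1, 1), (0.5,) * 3, 5.0, 3)
    assert len(open_c.parts()) == 5 and len(closed_c.parts()) == 5
    # open container's base sits at the bottom; closed container's at the top
    assert open_c.parts()[-1][0][2] < 0 < closed_c.parts()[-1][0][2]


def test_body_state_quaternion_must_be_unit():
    with pytest.raises(ValueError):
        w.BodyState([0, 0, 0], [0, 0, 0], [1, 1, 0, 0])


def test_mask_label_roundtrip():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 4, (3, 8, 8)).astype(np.uint8)
    masks = w.labels_to_masks(labels, 4)
    assert (masks.sum(axis=1) == 1).all()
    assert np.array_equal(w.masks_to_labels(masks), labels)


# --------------------------------------------------------------------------
# camera
# --------------------------------------------------------------------------

def test_drift_camera_contract():
    track = w.drift_camera(3, 10)
    assert np.array_equal(track.positions[0], w.CANONICAL_CAM_POS)
    lo, hi = w.DRIFT_BOUNDS
    assert (track.positions >= lo - 1e-9).all()
    assert (track.positions <= hi + 1e-9).all()
    assert np.allclose(np.linalg.norm(track.quats, axis=1), 1.0)
    again = w.drift_camera(3, 10)
    assert np.array_equal(track.positions, again.positions)

    single = w.drift_camera(3, 1)
    assert len(single) == 1
    zero = w.drift_camera(5, 8, bounds=(w.CANONICAL_CAM_POS, w.CANONICAL_CAM_POS))
    assert np.ptp(zero.positions, axis=0).max() == 0


def test_camera_encoding_is_position_plus_quaternion():
    track = w.canonical_camera(4)
    enc = track.encode()
    assert enc.shape == (4, 7)
    assert np.allclose(enc[:, :3], w.CANONICAL_CAM_POS)


# --------------------------------------------------------------------------
# renderer
# --------------------------------------------------------------------------

def test_golden_render_red_box():
    bodies = [{"shape": "box", "size": (1.0, 1.0, 1.0), "color": (0.85, 0.1, 0.1),
               "position": np.array([0, 0, 0.5]), "orientation": w.QUAT_ID,
               "channel": 1}]
    pose = (w.CANONICAL_CAM_POS, w.look_at_quat(w.CANONICAL_CAM_POS,
                                                w.CANONICAL_CAM_TARGET))
    img, owner = w.render_frame(bodies, pose, ((0.2, 0.2, 0.2), (0.9, 0.9, 0.85)),
                                H=16, W=16)
    golden = np.loadtxt(GOLDEN, delimiter=",", dtype=np.uint8).reshape(16, 16, 3)
    assert np.array_equal(w.image_to_uint8(img), golden)
    assert set(np.unique(owner)) == {0, 1}


def test_occluded_object_has_empty_mask_channel():
    # a sphere fully behind a curtain owns no pixels that frame
    curtain = {"shape": "curtain", "size": (3.0, 0.1, 3.0), "color": (0.1, 0.6, 0.1),
               "position": np.array([0, -1.0, 1.5]), "orientation": w.QUAT_ID,
               "channel": 1}
    sphere = {"shape": "sphere", "size": (0.6, 0.6, 0.6), "color": (0.9, 0.1, 0.1),
              "position": np.array([0, 0.5, 0.3]), "orientation": w.QUAT_ID,
              "channel": 2}
    pose = (w.CANONICAL_CAM_POS, w.look_at_quat(w.CANONICAL_CAM_POS,
                                                np.array([0, 0, 0.8])))
    _, owner = w.render_frame([curtain, sphere], pose, ((0.3,) * 3, (0.8,) * 3))
    assert (owner == 2).sum() == 0 and (owner == 1).sum() > 0


def test_overlapping_objects_nearer_owns_contested_pixels():
    near = {"shape": "sphere", "size": (0.8,) * 3, "color": (0.9, 0.1, 0.1),
            "position": np.array([0, -0.5, 0.4]), "orientation": w.QUAT_ID,
            "channel": 1}
    far = {"shape": "sphere", "size": (0.8,) * 3, "color": (0.1, 0.1, 0.9),
           "position": np.array([0.15, 1.0, 0.4]), "orientation": w.QUAT_ID,
           "channel": 2}
    pose = (w.CANONICAL_CAM_POS, w.look_at_quat(w.CANONICAL_CAM_POS,
                                                np.array([0, 0, 0.4])))
    _, owner = w.render_frame([near, far], pose, ((0.3,) * 3, (0.8,) * 3))
    # each pixel has exactly one owner by construction of the raycaster
    assert (owner == 1).sum() > (owner == 2).sum() > 0


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def test_empty_scene_is_floor_only(fx):
    rec = fx["videos"]["empty"]
    rec.validate()
    used = rec.masks.sum(axis=(0, 2, 3)).nonzero()[0]
    assert list(used) == [0]


def test_mask_partition_and_temporal_identity(fx):
    for rec in fx["videos"].values():
        rec.validate()          # partition: channels disjoint and exhaustive


def test_ballistic_flight_matches_closed_form():
    h0, r = 3.0, 0.3
    ball = w.ObjectSpec("sphere", (2 * r,) * 3, (1, 0, 0), 40.0, 1)
    spec = w.SceneSpec([(ball, w.BodyState([0, 0, h0], [0, 0, 0]),
                         w.Behavior("ballistic"))],
                       ((0.3,) * 3, (0.8,) * 3), "fixed", 0)
    rec = w.simulate_scene(spec, n_steps=3000, T=15, H=64, W=64, K=2)
    t = np.array(rec.meta["frame_times"])
    sim_z = rec.meta["positions"][:, 0, 2]
    analytic = np.maximum(h0 - 0.5 * spec.gravity * t ** 2, r)
    render_quantum = 8.0 / 64          # ~world units per pixel at scene depth
    assert np.abs(sim_z - analytic).max() < render_quantum


def test_speed_never_increases_except_gravity_and_scripts(fx):
    spec = fx["scenes"]["roll_and_reflect"]
    rec = w.simulate_scene(spec, n_steps=600, T=12, H=16, W=16, K=4)
    pos = rec.meta["positions"][:, 1]       # the rolling sphere
    dt = np.diff(rec.meta["frame_times"])
    speeds = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    assert speeds.max() <= speeds[0] + 1e-6


def test_simulation_is_deterministic():
    spec = w.sample_freeform_scene(7, w.SceneConfig())
    a = w.simulate_scene(spec, n_steps=400, T=10, H=32, W=32, K=8)
    b = w.simulate_scene(w.SceneSpec.from_dict(spec.to_dict()),
                         n_steps=400, T=10, H=32, W=32, K=8)
    assert np.array_equal(a.frames, b.frames)
    assert np.array_equal(a.masks, b.masks)


def test_nan_state_is_hard_failure():
    ball = w.ObjectSpec("sphere", (0.5,) * 3, (1, 0, 0), 10.0, 1)
    spec = w.SceneSpec([(ball, w.BodyState([0, 0, 1], [np.inf, 0, 0]),
                         w.Behavior("rolling"))],
                       ((0.3,) * 3, (0.8,) * 3), "fixed", 0)
    with pytest.raises(FloatingPointError):
        w.simulate_scene(spec, n_steps=100, T=5, H=8, W=8, K=2)


def test_offscreen_object_produces_warning():
    ball = w.ObjectSpec("sphere", (0.5,) * 3, (1, 0, 0), 10.0, 1)
    spec = w.SceneSpec([(ball, w.BodyState([500, 500, 0.25], [0, 0, 0]),
                         w.Behavior("static"))],
                       ((0.3,) * 3, (0.8,) * 3), "fixed", 0)
    rec = w.simulate_scene(spec, n_steps=50, T=5, H=16, W=16, K=2)
    assert rec.meta["warnings"]


# --------------------------------------------------------------------------
# freeform sampling
# --------------------------------------------------------------------------

def test_freeform_scene_composition_and_masses():
    for seed in range(6):
        spec = w.sample_freeform_scene(seed, w.SceneConfig())
        assert 2 <= len(spec.blocks) <= 4
        for obj, _, beh in spec.objects:
            if obj.shape in ("open_container", "closed_container"):
                assert obj.mass in w.MASS_CONTAINER
            elif beh.kind == "ballistic":
                assert obj.mass == w.MASS_DROPPED
            elif obj.shape == "arch":
                assert obj.mass == w.MASS_ARCH
        n_ids = len({o.object_id for o, _, _ in spec.objects})
        assert n_ids <= w.SceneConfig().K - 1      # one channel reserved


def test_rolling_block_can_target_a_stack_centre():
    """Composition through locations of interest: with composition forced,
    some sampled scene has a rolling sphere aimed at a stack's centre."""
    cfg = w.SceneConfig(enabled_blocks=("stack", "rolling"), compose_prob=1.0,
                        K=8)
    found = False
    for seed in range(40):
        spec = w.sample_freeform_scene(seed, cfg)
        stacks = [b["location"] for b in spec.blocks if b["block"] == "stack"]
        rollers = [b for b in spec.blocks
                   if b["block"] == "rolling" and b.get("composed")]
        for roll in rollers:
            if any(np.allclose(roll["target"][:2], s) for s in stacks):
                found = True
    assert found


def test_single_block_type_config():
    cfg = w.SceneConfig(enabled_blocks=("rolling",), K=8)
    spec = w.sample_freeform_scene(5, cfg)
    assert {b["block"] for b in spec.blocks} == {"rolling"}
    assert 2 <= len(spec.blocks) <= 4


def test_unsatisfiable_composition_raises():
    cfg = w.SceneConfig(enabled_blocks=("containment",), K=2, max_retries=3)
    with pytest.raises(w.GenerationError):
        w.sample_freeform_scene(0, cfg)


def test_scene_spec_roundtrip_and_hash_stability():
    spec = w.sample_freeform_scene(9, w.SceneConfig())
    again = w.sample_freeform_scene(9, w.SceneConfig())
    assert spec.hash() == again.hash()
    assert w.SceneSpec.from_dict(spec.to_dict()).hash() == spec.hash()
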