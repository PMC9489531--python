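"""Violation-of-expectation evaluation: surprise, tuple scoring, seed statistics.

Surprise for a video is the summed squared *pixel-space* error between the
decoded observed codes and the decoded predicted codes,

    surprise(video) = sum_{t=1}^{T-1} sum_{k=1}^{K} || Θ(z_k^{t+1}) - Θ(ẑ_k^{t+1}) ||²,

where Θ is the frozen perception decoder and Θ(z) the decoded object view
(image ⊙ mask). Pixel space rather than code space is used because empty
slots are coded near the unit-Gaussian prior with high variance: their codes
are hard to predict exactly, but every such code decodes to a blank view, so
pixel error ignores them. Within a tuple the possible and impossible videos
contain identical frames, so the usual size biases of pixel loss cancel.

A probe tuple is scored by summing surprise over its two possible and its
two impossible videos; it counts as correctly classified iff the impossible
sum is strictly greater (ties score 0), and the relative surprise
(imp - poss)/(imp + poss) in [-1, 1] quantifies the effect size. Seed-level
means are tested against chance (0 for relative surprise, 0.5 for accuracy)
with a one-tailed single-sample t test, df = n_seeds - 1, normal-theory 95%
confidence intervals.

Besides the trained predictor, three reference predictors support controls:
code persistence (copy-last), an untrained dynamics model, and an oracle
that memorises the possible videos' code sequences and predicts their
continuation after the longest matching suffix of the observed history —
which detects every splice and must classify every tuple correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import InteractionLSTM
from .perception import ComponentVAE
from .probes import ProbeTuple
from .world import VideoRecord


# --------------------------------------------------------------------------
# predictors
# --------------------------------------------------------------------------

class CopyLastPredictor:
    """ẑ^{t+1} = z^t: pure code persistence, the no-dynamics control."""

    def predict(self, codes: np.ndarray, cams: np.ndarray) -> np.ndarray:
        if codes.ndim == 3:
            return codes[:-1]
        return codes[:, :-1]


class OracleMemorizer:
    """Predicts the continuation of the memorised possible videos.

    Built per tuple from the possible videos' (deterministic, mean-encoded)
    code sequences. At each step it finds the longest suffix of the observed
    code history that matches a contiguous run in a possible video and
    predicts that video's next frame. Possible videos are predicted exactly;
    any spliced video deviates at least once after its violation onset.
    """

    def __init__(self, possible_code_seqs: list[np.ndarray]):
        self.memory = [np.ascontiguousarray(s.astype(np.float32))
                       for s in possible_code_seqs]
        self._keys = [[frame.tobytes() for frame in seq] for seq in self.memory]

    def predict(self, codes: np.ndarray, cams: np.ndarray) -> np.ndarray:
        if codes.ndim == 4:
            return np.stack([self.predict(c, cams[i])
                             for i, c in enumerate(codes)])
        T = codes.shape[0]
        obs_keys = [np.ascontiguousarray(codes[t].astype(np.float32)).tobytes()
                    for t in range(T)]
        preds = np.empty_like(codes[:-1])
        for t in range(T - 1):
            best_len, best = -1, codes[t]
            for seq, keys in zip(self.memory, self._keys):
                for i in range(len(keys)):
                    if keys[i] != obs_keys[t]:
                        continue
                    # suffix-match length ending at (t, i)
                    m = 0
                    while (m <= min(t, i)
                           and keys[i - m] == obs_keys[t - m]):
                        m += 1
                    if m > best_len:
                        best_len = m
                        best = seq[i + 1] if i + 1 < len(keys) else seq[i]
            preds[t] = best
        return preds


# --------------------------------------------------------------------------
# surprise
# --------------------------------------------------------------------------

@dataclass
class SurpriseTrace:
    per_frame: np.ndarray         # (T-1,) non-negative

    @property
    def total(self) -> float:
        return float(self.per_frame.sum())


def video_codes(video: VideoRecord, perception: ComponentVAE,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """(T,K,D) object codes: posterior samples if an rng is given, else means."""
    mu, lv = perception.encode_video(video)
    if rng is None:
        return mu.astype(np.float32)
    eps = rng.standard_normal(mu.shape)
    return (mu + np.exp(0.5 * lv) * eps).astype(np.float32)


def surprise(video: VideoRecord, perception: ComponentVAE, predictor,
             rng: np.random.Generator | None = None) -> SurpriseTrace:
    """Decoded-pixel prediction-error trace of one video under a predictor."""
    if video.T < 2:
        raise ValueError("surprise is undefined for videos shorter than 2 frames")
    z = video_codes(video, perception, rng)
    cams = video.camera.encode()
    zhat = predictor.predict(z, cams)
    obs = perception.object_views(z[1:])
    pred = perception.object_views(zhat)
    per_frame = ((obs - pred) ** 2).sum(axis=(1, 2, 3))
    return SurpriseTrace(per_frame.astype(np.float64))


# --------------------------------------------------------------------------
# tuple scoring
# --------------------------------------------------------------------------

@dataclass
class VoEResult:
    possible_surprise: float
    impossible_surprise: float
    relative_surprise: float
    accuracy: int
    possible_frames: np.ndarray = field(default=None, repr=False)
    impossible_frames: np.ndarray = field(default=None, repr=False)


def _relative(imp: float, poss: float) -> float:
    tot = imp + poss
    return (imp - poss) / tot if tot > 0 else 0.0


def score_tuple(tup: ProbeTuple, perception: ComponentVAE, predictor,
                rng: np.random.Generator | None = None) -> VoEResult:
    """Surprise sums over the tuple's videos; strict-greater classification.

    The tuple's four videos are encoded, predicted and decoded as one batch.
    Pass the string "oracle" to score against a per-tuple OracleMemorizer
    (which requires deterministic mean codes).
    """
    if isinstance(predictor, str) and predictor == "oracle":
        predictor = OracleMemorizer([video_codes(v, perception)
                                     for v in tup.possible])
        rng = None                      # the oracle needs deterministic codes
    vids = tup.all_videos()
    T = vids[0].T
    z = np.stack([video_codes(v, perception, rng) for v in vids])
    cams = np.stack([v.camera.encode() for v in vids])
    K, D = z.shape[2], z.shape[3]
    if isinstance(predictor, CopyLastPredictor):
        # ẑ^{t+1} = z^t: both decode sets are slices of one decoded sequence
        views = perception.object_views(z.reshape(4 * T, K, D))
        views = views.reshape(4, T, K, -1, 3)
        obs, pred = views[:, 1:], views[:, :-1]
        sse = ((obs - pred) ** 2).sum(axis=(2, 3, 4))
    else:
        zhat = predictor.predict(z, cams)                  # (4, T-1, K, D)
        obs = perception.object_views(z[:, 1:].reshape(4 * (T - 1), K, D))
        pred = perception.object_views(zhat.reshape(4 * (T - 1), K, D))
        sse = ((obs - pred) ** 2).sum(axis=(1, 2, 3)).reshape(4, T - 1)
    poss_f = sse[0] + sse[1]
    imp_f = sse[2] + sse[3]
    p, i = float(poss_f.sum()), float(imp_f.sum())
    return VoEResult(p, i, _relative(i, p), int(i > p),
                     poss_f.astype(np.float64), imp_f.astype(np.float64))


def evaluate_tuples(tuples: list[ProbeTuple], perception: ComponentVAE,
                    predictor, seed: int = 0,
                    use_samples: bool = True) -> list[VoEResult]:
    """Score many tuples; per-tuple rng derived from `seed` for determinism."""
    seq = np.random.SeedSequence(seed)
    out = []
    for tup, child in zip(tuples, seq.spawn(len(tuples))):
        rng = np.random.default_rng(child) if use_samples else None
        out.append(score_tuple(tup, perception, predictor, rng))
    return out


def framewise_relative_surprise(results: list[VoEResult]) -> np.ndarray:
    """Mean per-frame relative surprise curve over tuples.

    The tuple-level normalisation is applied framewise:
    (imp_f - poss_f) / (imp_f + poss_f) at each frame f.
    """
    curves = []
    for r in results:
        tot = r.impossible_frames + r.possible_frames
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(tot > 0, (r.impossible_frames - r.possible_frames)
                         / np.where(tot > 0, tot, 1.0), 0.0)
        curves.append(c)
    return np.mean(curves, axis=0)


# --------------------------------------------------------------------------
# seed-level statistics
# --------------------------------------------------------------------------

@dataclass
class SeedStats:
    per_seed: np.ndarray
    mean: float
    sd: float
    t: float
    p: float
    df: int
    ci95: tuple[float, float]
    null_value: float

    def to_dict(self) -> dict:
        return {"per_seed": self.per_seed.tolist(), "mean": self.mean,
                "sd": self.sd, "t": self.t, "p": self.p, "df": self.df,
                "ci95": list(self.ci95), "null_value": self.null_value}


def aggregate_seeds(per_seed_means, null_value: float) -> SeedStats:
    """One-sample, one-tailed t test of seed means against a chance value."""
    x = np.asarray(per_seed_means, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two seeds")
    m = float(x.mean())
    sd = float(x.std(ddof=1))
    se = sd / np.sqrt(n)
    t = (m - null_value) / se if se > 0 else (0.0 if m == null_value else np.inf)
    p = float(stats.t.sf(t, df=n - 1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * se
    return SeedStats(x, m, sd, float(t), p, n - 1, (m - half, m + half),
                     null_value)


def visual_experience(n_videos: int, seconds_per_video: float = 2.0,
                      wakeful_hours_per_day: float = 8.0) -> dict:
    """Convert a training-set size into equivalent visual experience."""
    seconds = n_videos * seconds_per_video
    return {
        "seconds": seconds,
        "hours": seconds / 3600.0,
        "continuous_days": seconds / 86_400.0,
        "wakeful_days": seconds / (3600.0 * wakeful_hours_per_day),
    }


# --------------------------------------------------------------------------
# full experiment
# --------------------------------------------------------------------------

def run_experiment(probe_sets: dict[str, list[ProbeTuple]],
                   perception: ComponentVAE,
                   dynamics_per_seed: list[InteractionLSTM],
                   seed: int = 0, use_samples: bool = True) -> dict:
    """Per-concept accuracy/relative-surprise tables with seed statistics.

    probe_sets maps concept -> probe tuples; each dynamics model corresponds
    to one training seed. Returns a JSON-serialisable report including
    framewise curves aligned on the violation onset.
    """
    report: dict = {"concepts": {}, "n_seeds": len(dynamics_per_seed)}
    grand_acc = np.zeros(len(dynamics_per_seed))
    grand_rel = np.zeros(len(dynamics_per_seed))
    for concept, tuples in probe_sets.items():
        accs, rels, curves = [], [], []
        for si, dyn in enumerate(dynamics_per_seed):
            results = evaluate_tuples(tuples, perception, dyn,
                                      seed=seed + 1000 * si,
                                      use_samples=use_samples)
            accs.append(np.mean([r.accuracy for r in results]))
            rels.append(np.mean([r.relative_surprise for r in results]))
            curves.append(framewise_relative_surprise(results))
        grand_acc += np.asarray(accs)
        grand_rel += np.asarray(rels)
        entry = {
            "n_tuples": len(tuples),
            "violation_onset": int(tuples[0].violation_onset[0]),
            "accuracy_per_seed": list(map(float, accs)),
            "relative_surprise_per_seed": list(map(float, rels)),
            "framewise_relative_surprise": np.mean(curves, axis=0).tolist(),
        }
        if len(dynamics_per_seed) >= 2:
            entry["accuracy_stats"] = aggregate_seeds(accs, 0.5).to_dict()
            entry["relative_surprise_stats"] = aggregate_seeds(rels, 0.0).to_dict()
        report["concepts"][concept] = entry
    n_c = len(probe_sets)
    report["grand_mean_accuracy"] = float(grand_acc.mean() / n_c)
    report["grand_mean_relative_surprise"] = float(grand_rel.mean() / n_c)
    report["grand_accuracy_per_seed"] = (grand_acc / n_c).tolist()
    return report
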