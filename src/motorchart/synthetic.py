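"""Synthetic cohort generator for motor label streams and physical growth.

Emulates the statistical structure that the downstream analyses assume:

* per-frame posture categories drawn from ``softmax(z_p(d))`` where the
  developmental stage ``d = age + delta_subject + eta_session`` combines the
  chronological age with a per-infant developmental offset
  (``N(0, sigma_dev^2)``) and a per-session situational offset
  (``N(0, sigma_sess^2)``);
* movement categories given posture from a cumulative-logit ordinal
  maturation model (still -> proto -> elementary -> fluent) plus small fixed
  probabilities for pivot/roll/transition;
* frame-to-frame persistence: each frame repeats the previous labels with
  probability ``p_stay``, otherwise both labels are redrawn;
* contiguous carried / low-quality / non-playtime blocks covering configured
  fractions of each session;
* monotone physical growth curves (length, weight, head circumference) with
  per-subject random intercepts and measurement error.

The generator also returns the latent ground truth (subject and session
offsets) so that parameter-recovery tests can compare estimates against the
values that generated the data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SyntheticConfig, hours_to_frames

# block-type codes used internally while laying out a session
_PLAY, _CARRIED, _LOWQ, _NONPLAY = 0, 1, 2, 3

STREAM_COLUMNS = [
    "frame_index", "posture", "movement",
    "carried_flag", "quality_flag", "playtime_truth",
]


@dataclasses.dataclass
class GroundTruth:
    """Latent variables behind a generated cohort."""

    subject_offsets: dict[str, float]
    session_offsets: dict[str, float]
    generating_params: dict


@dataclasses.dataclass
class MotorCohort:
    """A generated cohort: manifest plus per-recording label streams."""

    manifest: pd.DataFrame  # recording_id, subject_id, dataset_tag, age_months
    streams: dict[str, pd.DataFrame]

    def __len__(self) -> int:
        return len(self.manifest)


# ---------------------------------------------------------------------------
# Generating distributions (exposed so tests can use them as oracles)
# ---------------------------------------------------------------------------

def posture_probabilities(d: float, config: SyntheticConfig) -> np.ndarray:
    """Posture category probabilities softmax(z_p(d)) at stage ``d`` months."""
    z = np.array(
        [np.polyval(config.posture_trajectories[p][::-1], d) for p in config.postures]
    )
    z -= z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def movement_probabilities(d: float, config: SyntheticConfig) -> np.ndarray:
    """Posture x movement conditional probabilities at stage ``d``.

    Rows are postures, columns movements; each row sums to 1.  The ordinal
    block (still/proto/elementary/fluent) follows cumulative logits
    ``P(level >= j) = sigmoid(rate * (d - threshold_j - offset_p))`` and is
    rescaled to ``1 - sum(extras)``.
    """
    mat = config.movement_maturation
    rate = mat["rate"]
    thresholds = np.asarray(mat["thresholds"], dtype=float)
    movements = list(config.movements)
    ordinal = ["still", "proto", "elementary", "fluent"]
    out = np.zeros((len(config.postures), len(movements)))
    for i, posture in enumerate(config.postures):
        off = mat["posture_offsets"][posture]
        cum = 1.0 / (1.0 + np.exp(-rate * (d - thresholds - off)))  # P(>=1..3)
        probs = np.empty(4)
        probs[0] = 1.0 - cum[0]
        probs[1] = cum[0] - cum[1]
        probs[2] = cum[1] - cum[2]
        probs[3] = cum[2]
        extras = mat["extras"].get(posture, {})
        extra_mass = sum(extras.values())
        probs *= 1.0 - extra_mass
        for name, level in zip(ordinal, range(4)):
            out[i, movements.index(name)] = probs[level]
        for name, p in extras.items():
            out[i, movements.index(name)] = p
    return out


def _dist_vector(dist: dict[str, float], categories: tuple[str, ...]) -> np.ndarray:
    v = np.array([dist.get(c, 0.0) for c in categories], dtype=float)
    return v / v.sum()


# ---------------------------------------------------------------------------
# Frame-level simulation
# ---------------------------------------------------------------------------

def _block_layout(n_frames: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame block-type codes covering the configured fractions.

    The session is partitioned into contiguous blocks with geometric
    lengths; playtime and non-playtime periods use
    ``mean_play_block_minutes`` (long, as free play comes in extended
    bouts), carried and low-quality interruptions ``mean_block_minutes``.
    Block types are sampled in proportion to the remaining frame quota of
    each type.
    """
    quotas = np.array([
        round(config.playtime_fraction * n_frames),
        round(config.carried_fraction * n_frames),
        round(config.lowquality_fraction * n_frames),
        0,
    ], dtype=float)
    quotas[_NONPLAY] = max(n_frames - quotas[:3].sum(), 0.0)

    short_block = max(int(config.mean_block_minutes * 60.0 / 1.15), 1)
    long_block = max(int(config.mean_play_block_minutes * 60.0 / 1.15), 1)
    mean_by_type = (long_block, short_block, short_block, long_block)
    types = np.empty(n_frames, dtype=np.int8)
    pos = 0
    remaining = quotas.copy()
    while pos < n_frames:
        if remaining.sum() <= 0:
            remaining = quotas.copy()  # numerical guard; quotas sum to n_frames
        p = remaining / remaining.sum()
        btype = rng.choice(4, p=p)
        length = int(rng.geometric(1.0 / mean_by_type[btype]))
        length = min(length, n_frames - pos, int(remaining[btype]) or length)
        types[pos:pos + length] = btype
        remaining[btype] = max(remaining[btype] - length, 0.0)
        pos += length
    return types


def _sample_joint(n: int, posture_p: np.ndarray, cond_move: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` iid (posture, movement) index pairs from the joint model."""
    cum_p = np.cumsum(posture_p)
    postures = np.searchsorted(cum_p, rng.random(n), side="right")
    postures = np.clip(postures, 0, len(posture_p) - 1)
    cum_m = np.cumsum(cond_move, axis=1)
    u = rng.random(n)
    movements = (u[:, None] > cum_m[postures]).sum(axis=1)
    movements = np.clip(movements, 0, cond_move.shape[1] - 1)
    return postures, movements


def simulate_recording(config: SyntheticConfig, d: float, n_frames: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Simulate one recording's frame-label stream at developmental stage ``d``.

    Frames carry posture/movement labels regardless of block type; carried
    and non-playtime frames are drawn from the age-independent resting
    distribution, playtime frames from the stage-``d`` model.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    block = _block_layout(n_frames, config, rng)

    play_pp = posture_probabilities(d, config)
    play_cm = movement_probabilities(d, config)
    rest_pp = _dist_vector(config.nonplay_distribution["posture"], config.postures)
    rest_mv = _dist_vector(config.nonplay_distribution["movement"], config.movements)
    rest_cm = np.tile(rest_mv, (len(config.postures), 1))

    redraw = rng.random(n_frames) >= config.p_stay
    redraw[0] = True
    boundary = np.empty(n_frames, dtype=bool)
    boundary[0] = True
    boundary[1:] = block[1:] != block[:-1]
    redraw |= boundary  # persistence does not cross block boundaries

    event_idx = np.flatnonzero(redraw)
    event_block = block[event_idx]
    is_play = event_block == _PLAY
    post_ev = np.empty(len(event_idx), dtype=np.int64)
    move_ev = np.empty(len(event_idx), dtype=np.int64)
    n_play = int(is_play.sum())
    if n_play:
        post_ev[is_play], move_ev[is_play] = _sample_joint(n_play, play_pp, play_cm, rng)
    n_rest = len(event_idx) - n_play
    if n_rest:
        post_ev[~is_play], move_ev[~is_play] = _sample_joint(n_rest, rest_pp, rest_cm, rng)

    run = np.cumsum(redraw) - 1
    postures = np.asarray(config.postures)[post_ev[run]]
    movements = np.asarray(config.movements)[move_ev[run]]

    return pd.DataFrame({
        "frame_index": np.arange(n_frames),
        "posture": postures,
        "movement": movements,
        "carried_flag": block == _CARRIED,
        "quality_flag": block != _LOWQ,
        "playtime_truth": block == _PLAY,
    })


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _session_hours(config: SyntheticConfig, rng: np.random.Generator) -> float:
    sh = config.session_hours
    h = rng.normal(sh["mean"], sh["sd"])
    return float(np.clip(h, sh["min"], sh["max"]))


def generate_motor_cohort(config: SyntheticConfig,
                          seed: int | None = None) -> tuple[MotorCohort, GroundTruth]:
    """Generate a cohort of frame-label streams plus its latent ground truth.

    Each subject receives a developmental offset ``delta_i ~ N(0, sigma_dev^2)``
    and each recording a situational offset ``eta_r ~ N(0, sigma_sess^2)``;
    labels are drawn at stage ``d = age + delta_i + eta_r``.  Identical
    ``(config, seed)`` produce identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.age_range_months
    rmin, rmax = config.recordings_per_subject

    rows = []
    streams: dict[str, pd.DataFrame] = {}
    subject_offsets: dict[str, float] = {}
    session_offsets: dict[str, float] = {}
    for i in range(config.n_subjects):
        subject_id = f"{config.dataset_tag}-S{i:04d}"
        delta = rng.normal(0.0, config.sigma_dev)
        subject_offsets[subject_id] = float(delta)
        n_rec = int(rng.integers(rmin, rmax + 1))
        ages = np.sort(rng.uniform(lo, hi, size=n_rec))
        for j, age in enumerate(ages):
            rec_id = f"{subject_id}-R{j:02d}"
            eta = rng.normal(0.0, config.sigma_sess)
            session_offsets[rec_id] = float(eta)
            n_frames = hours_to_frames(_session_hours(config, rng))
            d = float(age + delta + eta)
            streams[rec_id] = simulate_recording(config, d, n_frames, rng)
            rows.append({
                "recording_id": rec_id,
                "subject_id": subject_id,
                "dataset_tag": config.dataset_tag,
                "age_months": float(age),
            })
    manifest = pd.DataFrame(rows)
    truth = GroundTruth(
        subject_offsets=subject_offsets,
        session_offsets=session_offsets,
        generating_params={
            "posture_trajectories": config.posture_trajectories,
            "movement_maturation": config.movement_maturation,
            "physical_curves": config.physical_curves,
        },
    )
    return MotorCohort(manifest=manifest, streams=streams), truth


# ---------------------------------------------------------------------------
# Physical growth
# ---------------------------------------------------------------------------

_VISIT_SCHEDULE = np.array([4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 18.0])


def median_curve(t: np.ndarray, params: dict[str, float]) -> np.ndarray:
    """Evaluate a configured monotone median growth curve mu_k(t)."""
    t = np.asarray(t, dtype=float)
    form = params["form"]
    if form == "linear_log":
        return params["a"] + params["b"] * np.log1p(t / params["t0"])
    if form == "power":
        return params["a"] + params["b"] * t ** params["c"]
    raise ValueError(f"unknown median-curve form {form!r}")


def _check_monotone(params: dict[str, float], age_range: tuple[float, float]) -> None:
    grid = np.linspace(age_range[0], age_range[1], 200)
    mu = median_curve(grid, params)
    if not np.all(np.diff(mu) > 0):
        raise ValueError(f"configured median curve is not strictly increasing: {params}")


def generate_physical_cohort(config: SyntheticConfig,
                             seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate serial length/weight/HC measurements with random intercepts.

    Each measurement is ``mu_k(t) + b_ik + e``, with ``b_ik ~ N(0, sigma_subj^2)``
    per subject and modality and ``e ~ N(0, sigma_meas^2)`` per visit.  Visit
    ages follow the routine child-health-clinic schedule restricted to the
    configured age range, with small uniform jitter.
    """
    config.validate()
    for params in config.physical_curves.values():
        _check_monotone(params, config.age_range_months)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    lo, hi = config.age_range_months
    schedule = _VISIT_SCHEDULE[(_VISIT_SCHEDULE >= lo) & (_VISIT_SCHEDULE <= hi)]
    if len(schedule) == 0:
        schedule = np.linspace(lo, hi, 4)
    vmin, vmax = config.visits_per_subject
    modalities = list(config.physical_curves)

    rows = []
    subject_offsets: dict[str, dict[str, float]] = {}
    for i in range(config.n_subjects):
        subject_id = f"{config.dataset_tag}-P{i:05d}"
        b = {k: float(rng.normal(0.0, config.physical_curves[k]["sigma_subj"]))
             for k in modalities}
        subject_offsets[subject_id] = b
        n_visits = int(rng.integers(vmin, min(vmax, len(schedule)) + 1))
        ages = rng.choice(schedule, size=n_visits, replace=False)
        ages = np.sort(ages + rng.uniform(-0.25, 0.25, size=n_visits))
        ages = np.clip(ages, lo, hi)
        for t in ages:
            row = {"subject_id": subject_id, "age_months": float(t)}
            for k in modalities:
                mu = float(median_curve(np.array([t]), config.physical_curves[k])[0])
                e = float(rng.normal(0.0, config.physical_curves[k]["sigma_meas"]))
                row[k] = mu + b[k] + e
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        subject_offsets={s: b for s, b in subject_offsets.items()},
        session_offsets={},
        generating_params={"physical_curves": config.physical_curves},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Disk round-trip (delimited text only)
# ---------------------------------------------------------------------------

def write_motor_cohort(cohort: MotorCohort, truth: GroundTruth, out_dir) -> Path:
    out = Path(out_dir)
    (out / "streams").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for rec_id in manifest["recording_id"]:
        rel = f"streams/{rec_id}.csv"
        cohort.streams[rec_id].to_csv(out / rel, index=False)
        paths.append(rel)
    manifest["stream_path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(
        {"subject_id": list(truth.subject_offsets),
         "offset_months": list(truth.subject_offsets.values())}
    ).to_csv(out / "subject_offsets.csv", index=False)
    pd.DataFrame(
        {"recording_id": list(truth.session_offsets),
         "offset_months": list(truth.session_offsets.values())}
    ).to_csv(out / "session_offsets.csv", index=False)
    return out


def read_motor_cohort(in_dir) -> MotorCohort:
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    streams = {}
    for _, row in manifest.iterrows():
        df = pd.read_csv(src / row["stream_path"])
        for col in ("carried_flag", "quality_flag", "playtime_truth"):
            df[col] = df[col].astype(bool)
        streams[row["recording_id"]] = df
    return MotorCohort(manifest=manifest.drop(columns=["stream_path"]), streams=streams)
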