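"""Recording-level motor features: posture and posture-conditioned movement
distributions, their fixed-order flattening, and monthly mean curves."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import config as cfg


@dataclasses.dataclass
class MotorFeatures:
    """Distribution features of one recording's analysable playtime frames.

    ``posture_fractions`` sums to 1; each row of ``conditional_movement``
    sums to 1 where the posture was observed and is all-zero where it was
    not (keeping the flattened feature space fixed-dimensional).
    """

    recording_id: str
    posture_fractions: np.ndarray            # (P,)
    conditional_movement: np.ndarray         # (P, M), rows sum to 1 or 0
    analysed_hours: float
    postures: tuple[str, ...] = cfg.POSTURES
    movements: tuple[str, ...] = cfg.MOVEMENTS

    def overall_movement(self) -> np.ndarray:
        """Movement-category fractions on the common (whole-recording) scale:
        conditional rows weighted by their posture prevalence."""
        return self.posture_fractions @ self.conditional_movement


def compute_features(frames: pd.DataFrame, recording_id: str = "",
                     postures: tuple[str, ...] = cfg.POSTURES,
                     movements: tuple[str, ...] = cfg.MOVEMENTS,
                     hop_seconds: float = cfg.HOP_SECONDS) -> MotorFeatures:
    """Posture and posture-conditioned movement distributions of a frame set."""
    n = len(frames)
    if n == 0:
        raise ValueError("cannot compute features of an empty frame set "
                         "(recording should have been excluded upstream)")
    p_idx = pd.Categorical(frames["posture"], categories=postures).codes
    m_idx = pd.Categorical(frames["movement"], categories=movements).codes
    if (p_idx < 0).any() or (m_idx < 0).any():
        raise ValueError("frame labels outside the configured category inventory")
    P, M = len(postures), len(movements)
    joint = np.zeros((P, M))
    np.add.at(joint, (p_idx, m_idx), 1.0)
    posture_counts = joint.sum(axis=1)
    posture_fractions = posture_counts / n
    conditional = np.zeros_like(joint)
    observed = posture_counts > 0
    conditional[observed] = joint[observed] / posture_counts[observed, None]
    return MotorFeatures(
        recording_id=recording_id,
        posture_fractions=posture_fractions,
        conditional_movement=conditional,
        analysed_hours=n * hop_seconds / 3600.0,
        postures=tuple(postures),
        movements=tuple(movements),
    )


def flatten_features(f: MotorFeatures) -> np.ndarray:
    """Deterministic feature vector: [posture_fractions ; row-major conditional].

    With 6 postures and 7 movements the vector has 6 + 42 = 48 entries; the
    ordering follows the configured category inventory and is stable across
    runs.
    """
    return np.concatenate([f.posture_fractions, f.conditional_movement.ravel()])


def unflatten_features(vec: np.ndarray, recording_id: str = "",
                       postures: tuple[str, ...] = cfg.POSTURES,
                       movements: tuple[str, ...] = cfg.MOVEMENTS) -> MotorFeatures:
    """Inverse of :func:`flatten_features` (validates the dimension)."""
    P, M = len(postures), len(movements)
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (P + P * M,):
        raise ValueError(f"feature vector length {vec.shape} does not match "
                         f"{P} postures x {M} movements")
    return MotorFeatures(
        recording_id=recording_id,
        posture_fractions=vec[:P].copy(),
        conditional_movement=vec[P:].reshape(P, M).copy(),
        analysed_hours=float("nan"),
        postures=tuple(postures),
        movements=tuple(movements),
    )


def feature_table(features: list[MotorFeatures]) -> pd.DataFrame:
    """One row per recording with explicitly named category cells."""
    if not features:
        return pd.DataFrame()
    postures, movements = features[0].postures, features[0].movements
    cols = [f"posture_{p}" for p in postures]
    cols += [f"cond_{p}_{m}" for p in postures for m in movements]
    data = np.vstack([flatten_features(f) for f in features])
    out = pd.DataFrame(data, columns=cols)
    out.insert(0, "recording_id", [f.recording_id for f in features])
    out["analysed_hours"] = [f.analysed_hours for f in features]
    return out


def agegroup_mean_curves(features: list[MotorFeatures], ages: np.ndarray,
                         bin_start: int = 4, bin_stop: int = 18,
                         weight_movement_by_posture: bool = True) -> pd.DataFrame:
    """Per-category mean fraction per monthly age bin [m, m+1).

    Posture categories are averaged directly; movement categories are, by
    default, reported on the common whole-recording scale (conditional rows
    weighted by posture prevalence) so posture and movement curves share
    units.  Empty bins are flagged with NaN means and n=0.
    """
    ages = np.asarray(ages, dtype=float)
    if len(features) != len(ages):
        raise ValueError("features and ages length mismatch")
    postures = features[0].postures
    movements = features[0].movements
    cat_names = [f"posture_{p}" for p in postures]
    if weight_movement_by_posture:
        cat_names += [f"movement_{m}" for m in movements]
        per_rec = np.vstack([
            np.concatenate([f.posture_fractions, f.overall_movement()])
            for f in features
        ])
    else:
        cat_names += [f"cond_{p}_{m}" for p in postures for m in movements]
        per_rec = np.vstack([
            np.concatenate([f.posture_fractions, f.conditional_movement.ravel()])
            for f in features
        ])
    rows = []
    for m in range(bin_start, bin_stop + 1):
        in_bin = (ages >= m) & (ages < m + 1)
        n = int(in_bin.sum())
        if n:
            means = per_rec[in_bin].mean(axis=0)
        else:
            means = np.full(per_rec.shape[1], np.nan)
        row = {"bin_start": m, "bin_mid": m + 0.5, "n": n}
        row.update(dict(zip(cat_names, means)))
        rows.append(row)
    return pd.DataFrame(rows)
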