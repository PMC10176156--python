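"""Measurement-noise estimation and longitudinal DAP tracking.

Intra-session noise: recordings with more than 2 h of free playtime are
split into consecutive non-overlapping 1-h playtime epochs, each scored
with its own DAP; the SD of within-recording epoch differences, divided by
sqrt(2), estimates the per-epoch measurement noise (two independent
equal-variance epochs give Var(diff) = 2 sigma^2).

Longitudinal tracking: for every subject with repeat recordings, all
ordered pairs (t0 < t1) yield (delta_age, delta_DAP); monthly bins of
delta_age summarize the mean developmental advance and its spread.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .config import EPOCH_MIN_PLAYTIME_HOURS, HOP_SECONDS, hours_to_frames


def split_epochs(analysable_frames: pd.DataFrame,
                 min_playtime_hours: float = EPOCH_MIN_PLAYTIME_HOURS,
                 epoch_hours: float = 1.0,
                 hop_seconds: float = HOP_SECONDS) -> list[pd.DataFrame]:
    """Split a recording's analysable playtime into non-overlapping epochs.

    Only recordings with *strictly more* than ``min_playtime_hours`` of
    retained playtime qualify; the trailing partial epoch is discarded.
    """
    n = len(analysable_frames)
    retained_hours = n * hop_seconds / 3600.0
    if retained_hours <= min_playtime_hours:
        return []
    epoch_frames = hours_to_frames(epoch_hours)
    n_epochs = n // epoch_frames
    return [analysable_frames.iloc[i * epoch_frames:(i + 1) * epoch_frames]
            for i in range(n_epochs)]


@dataclasses.dataclass
class NoiseEstimate:
    """Within-recording DAP variability between 1-h epochs."""

    session_pairs: pd.DataFrame  # recording_id, epoch_i, epoch_j, dap_diff, age_months
    sigma_noise: float           # months; SD(diffs) / sqrt(2)
    ks_p: float                  # K-S test of standardized diffs vs N(0,1)
    age_corr_r: float            # Pearson r of |diff| (or signed diff) vs age
    age_corr_p: float
    n_pairs: int


def intra_session_noise(epoch_daps: pd.DataFrame,
                        signed_age_corr: bool = False) -> NoiseEstimate:
    """Estimate per-epoch DAP measurement noise from within-recording pairs.

    ``epoch_daps`` needs columns recording_id, epoch_index, dap_months,
    age_months.  All unordered epoch pairs within each recording contribute
    one difference; ``sigma_noise = SD(diffs)/sqrt(2)``.  Normality of the
    standardized differences is tested with a one-sample K-S test, and the
    age dependence of the noise level as Pearson r of |diff| against age.
    """
    rows = []
    for rec_id, grp in epoch_daps.groupby("recording_id", sort=False):
        grp = grp.sort_values("epoch_index")
        for (ia, a), (ib, b) in itertools.combinations(grp.iterrows(), 2):
            rows.append({
                "recording_id": rec_id,
                "epoch_i": int(a["epoch_index"]),
                "epoch_j": int(b["epoch_index"]),
                "dap_diff": float(b["dap_months"] - a["dap_months"]),
                "age_months": float(a["age_months"]),
            })
    pairs = pd.DataFrame(rows)
    if len(pairs) < 2:
        raise ValueError("need >= 2 within-recording epoch pairs for noise estimation")
    diffs = pairs["dap_diff"].to_numpy()
    sd = float(np.std(diffs, ddof=1))
    sigma_noise = sd / np.sqrt(2.0)
    if sd > 0:
        z = (diffs - diffs.mean()) / sd
        ks_p = float(stats.kstest(z, "norm").pvalue)
    else:
        ks_p = float("nan")
    level = diffs if signed_age_corr else np.abs(diffs)
    if np.ptp(level) > 0 and np.ptp(pairs["age_months"].to_numpy()) > 0:
        r, p = stats.pearsonr(level, pairs["age_months"])
    else:
        r, p = float("nan"), float("nan")
    return NoiseEstimate(session_pairs=pairs, sigma_noise=float(sigma_noise),
                         ks_p=ks_p, age_corr_r=float(r), age_corr_p=float(p),
                         n_pairs=len(pairs))


def pair_deltas(dap_table: pd.DataFrame) -> pd.DataFrame:
    """All within-subject ordered pairs (t1 > t0) of DAP measurements.

    ``dap_table`` needs columns subject_id, age_months, dap_months.  A
    subject with k recordings contributes k(k-1)/2 pairs.  Columns out:
    subject_id, age_t0, delta_age, delta_dap.
    """
    rows = []
    for subject, grp in dap_table.groupby("subject_id", sort=False):
        grp = grp.sort_values("age_months")
        ages = grp["age_months"].to_numpy()
        daps = grp["dap_months"].to_numpy()
        for i, j in itertools.combinations(range(len(grp)), 2):
            rows.append({
                "subject_id": subject,
                "age_t0": float(ages[i]),
                "delta_age": float(ages[j] - ages[i]),
                "delta_dap": float(daps[j] - daps[i]),
            })
    return pd.DataFrame(rows, columns=["subject_id", "age_t0", "delta_age", "delta_dap"])


@dataclasses.dataclass
class DeltaBinStats:
    table: pd.DataFrame          # bin_start, n, mean, sd, flagged
    monotone_means: bool         # over bins passing min_count


def delta_bin_stats(pairs: pd.DataFrame, bin_width: float = 1.0,
                    bin_start: float = 1.0, bin_stop: float = 10.0,
                    min_count: int = 3) -> DeltaBinStats:
    """Per-bin mean and SD of delta_DAP over monthly delta_age bins [m, m+1).

    Bins with fewer than ``min_count`` pairs are flagged and excluded from
    the monotonicity assessment of the bin means.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one measurement pair")
    edges = np.arange(bin_start, bin_stop + bin_width, bin_width)
    rows = []
    for lo in edges:
        sel = (pairs["delta_age"] >= lo) & (pairs["delta_age"] < lo + bin_width)
        d = pairs.loc[sel, "delta_dap"].to_numpy()
        rows.append({
            "bin_start": float(lo),
            "n": int(sel.sum()),
            "mean": float(d.mean()) if len(d) else float("nan"),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
            "flagged": bool(len(d) < min_count),
        })
    table = pd.DataFrame(rows)
    ok = table[~table["flagged"]]
    monotone = bool(np.all(np.diff(ok["mean"].to_numpy()) >= 0)) if len(ok) > 1 else True
    return DeltaBinStats(table=table, monotone_means=monotone)
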