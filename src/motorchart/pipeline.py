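"""End-to-end experiment orchestration.

Stages: generate (synthetic cohorts) -> process/features (playtime
detection, retention accounting, recording-level features) -> exp1
(between-cohort replicability and measurement noise) -> exp2 (motor and
physical DAP growth charts) -> exp3 (longitudinal delta-DAP tracking).
Every stage writes delimited-text tables under the run directory and a
manifest records seeds and versions; reruns with the same config are
reproducible from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .config import EPOCH_MIN_PLAYTIME_HOURS, MIN_PLAYTIME_HOURS, SyntheticConfig
from .compare import compare_category_curves, compare_dap_models
from .chart import build_chart
from .dap import DAPDataset, fit_dap, loso_cv, physical_dap, predict_dap
from .features import agegroup_mean_curves, compute_features, feature_table, flatten_features
from .streams import (cohort_sessions, detect_playtime, select_analysis_frames,
                      super_segments, train_playtime_classifier)
from .synthetic import generate_motor_cohort, generate_physical_cohort, write_motor_cohort
from .variability import delta_bin_stats, intra_session_noise, pair_deltas, split_epochs

logger = logging.getLogger("motorchart")

EXPERIMENTS = ("exp1", "exp2", "exp3", "all")
MODALITIES = ("motor", "length", "weight", "hc", "physical3")
PHYSICAL_COLUMNS = {
    "length": ["length_cm"],
    "weight": ["weight_kg"],
    "hc": ["hc_cm"],
    "physical3": ["length_cm", "weight_kg", "hc_cm"],
}


@dataclasses.dataclass
class RunConfig:
    """Scale knobs, seeds and module parameters for one pipeline run."""

    out_dir: str = "motorchart_run"
    seed: int = 0
    n_subjects_motor: int = 40          # per dataset (DS1 / DS2)
    n_subjects_physical: int = 150
    n_boot: int = 500                    # bootstrap resamples for chart CIs
    n_boot_id: int = 150                 # resamples for ID-controlled CIs
    loso_folds: int | None = 10          # None = full leave-one-subject-out
    physical_folds: int = 5
    gpr_restarts: int = 2
    min_playtime_hours: float = MIN_PLAYTIME_HOURS
    epoch_min_playtime_hours: float = EPOCH_MIN_PLAYTIME_HOURS
    use_detected_playtime: bool = True
    synthetic_overrides: dict = dataclasses.field(default_factory=dict)

    def motor_config(self, tag: str, seed_offset: int) -> SyntheticConfig:
        return SyntheticConfig(
            n_subjects=self.n_subjects_motor, dataset_tag=tag,
            seed=self.seed + seed_offset, **self.synthetic_overrides)

    def physical_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            n_subjects=self.n_subjects_physical, dataset_tag="GROWTH",
            seed=self.seed + 17, **self.synthetic_overrides)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing input {path}; produce it first by running stage {stage!r}")
    return path


class Pipeline:
    """Stateful runner binding a RunConfig to a run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._cohorts = None     # in-memory cache within one process

    # -- stage: generate ----------------------------------------------------

    def stage_generate(self) -> dict:
        cfg = self.config
        ds1, _ = generate_motor_cohort(cfg.motor_config("DS1", 1))
        ds2, truth2 = generate_motor_cohort(cfg.motor_config("DS2", 2))
        physical, _ = generate_physical_cohort(cfg.physical_config())
        data = self.out / "data"
        write_motor_cohort(ds1, _, data / "ds1")
        write_motor_cohort(ds2, truth2, data / "ds2")
        physical.to_csv(data / "physical.csv", index=False)
        self._cohorts = {"DS1": ds1, "DS2": ds2, "physical": physical}
        return {"ds1_recordings": len(ds1), "ds2_recordings": len(ds2),
                "physical_rows": len(physical)}

    # -- stage: process + features ------------------------------------------

    def _train_playtime(self, sessions, seed: int):
        feats, labels = [], []
        for rec in sessions:
            for w in super_segments(rec.frames):
                truth = rec.frames["playtime_truth"].to_numpy()[w.start_frame:w.end_frame]
                feats.append(w.features)
                labels.append(int(truth.mean() >= 0.5))
        return train_playtime_classifier(np.vstack(feats), np.array(labels), seed=seed)

    def stage_features(self) -> dict:
        if self._cohorts is None:
            _require(self.out / "data" / "ds1" / "manifest.csv", "generate")
            from .synthetic import read_motor_cohort
            self._cohorts = {
                "DS1": read_motor_cohort(self.out / "data" / "ds1"),
                "DS2": read_motor_cohort(self.out / "data" / "ds2"),
                "physical": pd.read_csv(_require(self.out / "data" / "physical.csv",
                                                 "generate")),
            }
        cfg = self.config
        sessions1 = cohort_sessions(self._cohorts["DS1"])
        classifier = self._train_playtime(sessions1, seed=cfg.seed + 3)

        report_rows, accounting = [], []
        for tag in ("DS1", "DS2"):
            sessions = cohort_sessions(self._cohorts[tag])
            features, epoch_rows = [], []
            for rec in sessions:
                total_hours = len(rec.frames) * rec.hop_seconds / 3600.0
                if cfg.use_detected_playtime:
                    mask = detect_playtime(super_segments(rec.frames), classifier,
                                           len(rec.frames)).mask
                else:
                    mask = None
                sel = select_analysis_frames(rec, playtime_mask=mask,
                                             min_playtime_hours=cfg.min_playtime_hours)
                accounting.append({
                    "recording_id": rec.recording_id, "dataset_tag": tag,
                    "subject_id": rec.subject_id, "age_months": rec.age_months,
                    "total_hours": round(total_hours, 3),
                    "retained_hours": round(sel.retained_hours, 3),
                    "excluded": sel.excluded, "reason": sel.reason,
                })
                if sel.excluded:
                    continue
                f = compute_features(sel.frames, recording_id=rec.recording_id)
                features.append((rec, f))
                for e_idx, epoch in enumerate(split_epochs(
                        sel.frames, min_playtime_hours=cfg.epoch_min_playtime_hours)):
                    ef = compute_features(epoch, recording_id=rec.recording_id)
                    epoch_rows.append({
                        "recording_id": rec.recording_id, "subject_id": rec.subject_id,
                        "dataset_tag": tag, "age_months": rec.age_months,
                        "epoch_index": e_idx,
                        **dict(enumerate(flatten_features(ef))),
                    })
            table = feature_table([f for _, f in features])
            meta = pd.DataFrame({
                "recording_id": [r.recording_id for r, _ in features],
                "subject_id": [r.subject_id for r, _ in features],
                "dataset_tag": tag,
                "age_months": [r.age_months for r, _ in features],
            })
            table = meta.merge(table, on="recording_id")
            table.to_csv(self.out / f"features_{tag.lower()}.csv", index=False)
            pd.DataFrame(epoch_rows).to_csv(
                self.out / f"epoch_features_{tag.lower()}.csv", index=False)
            report_rows.append({"dataset_tag": tag, "n_recordings": len(sessions),
                                "n_analysable": len(features)})
        pd.DataFrame(accounting).to_csv(self.out / "retention_report.csv", index=False)
        return {"cohorts": report_rows}

    # -- helpers ------------------------------------------------------------

    def _feature_dataset(self, tag: str) -> DAPDataset:
        path = _require(self.out / f"features_{tag.lower()}.csv", "features")
        table = pd.read_csv(path)
        feat_cols = [c for c in table.columns if c.startswith(("posture_", "cond_"))]
        return DAPDataset(
            X=table[feat_cols].to_numpy(dtype=float),
            ages=table["age_months"].to_numpy(dtype=float),
            subject_ids=table["subject_id"].to_numpy(),
            recording_ids=table["recording_id"].to_numpy(),
            tag=tag,
        )

    def _pooled_dataset(self) -> DAPDataset:
        a, b = self._feature_dataset("DS1"), self._feature_dataset("DS2")
        return DAPDataset(
            X=np.vstack([a.X, b.X]),
            ages=np.concatenate([a.ages, b.ages]),
            subject_ids=np.concatenate([a.subject_ids, b.subject_ids]),
            recording_ids=np.concatenate([a.recording_ids, b.recording_ids]),
            tag="DS1+DS2",
        )

    def _motor_dap_table(self) -> pd.DataFrame:
        cached = self.out / "dap_motor.csv"
        if cached.exists():
            return pd.read_csv(cached)
        cfg = self.config
        pooled = self._pooled_dataset()
        results = loso_cv(pooled, seed=cfg.seed, n_restarts=cfg.gpr_restarts,
                          n_folds=cfg.loso_folds)
        results.to_csv(cached, index=False)
        return results

    # -- experiment 1 -------------------------------------------------------

    def exp1(self) -> dict:
        cfg = self.config
        curves, feats = {}, {}
        for tag in ("DS1", "DS2"):
            path = _require(self.out / f"features_{tag.lower()}.csv", "features")
            table = pd.read_csv(path)
            cols = [c for c in table.columns if c.startswith(("posture_", "cond_"))]
            fobjs = []
            from .features import unflatten_features
            for _, row in table.iterrows():
                fobjs.append(unflatten_features(row[cols].to_numpy(dtype=float),
                                                recording_id=row["recording_id"]))
            curves[tag] = agegroup_mean_curves(fobjs, table["age_months"].to_numpy())
            feats[tag] = table
            curves[tag].to_csv(self.out / f"curves_{tag.lower()}.csv", index=False)
        comparison = compare_category_curves(curves["DS1"], curves["DS2"])
        comparison.per_category.to_csv(self.out / "exp1_category_agreement.csv", index=False)
        comparison.group_summary.to_csv(self.out / "exp1_group_summary.csv", index=False)

        dap_table = self._motor_dap_table()
        charts = {}
        for tag in ("DS1", "DS2"):
            sub = dap_table[dap_table["recording_id"].str.startswith(tag)]
            charts[tag] = build_chart(sub, f"motor-{tag}", n_boot=cfg.n_boot,
                                      n_boot_id=cfg.n_boot_id, seed=cfg.seed)
        agreement = compare_dap_models(charts["DS1"], charts["DS2"])

        epoch_daps = self._epoch_daps()
        noise = (intra_session_noise(epoch_daps)
                 if len(epoch_daps) else None)
        if noise is not None:
            noise.session_pairs.to_csv(self.out / "exp1_epoch_pairs.csv", index=False)
            self._plot_noise(noise)
        summary = {
            "category_agreement": comparison.group_summary.to_dict("records"),
            "agegroup_dap_r": agreement.agegroup_dap_r,
            "all_params_overlap": agreement.all_params_overlap,
            "params_overlap": agreement.params_overlap,
            "band_overlap_fraction": agreement.band_overlap_fraction,
            "noise_sigma_months": noise.sigma_noise if noise else None,
            "noise_ks_p": noise.ks_p if noise else None,
            "noise_age_corr_r": noise.age_corr_r if noise else None,
            "noise_n_pairs": noise.n_pairs if noise else 0,
        }
        (self.out / "exp1_summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    def _epoch_daps(self) -> pd.DataFrame:
        cfg = self.config
        pooled = self._pooled_dataset()
        model = fit_dap(pooled, seed=cfg.seed, n_restarts=cfg.gpr_restarts)
        frames = []
        for tag in ("DS1", "DS2"):
            path = self.out / f"epoch_features_{tag.lower()}.csv"
            if not path.exists():
                continue
            try:
                table = pd.read_csv(path)
            except pd.errors.EmptyDataError:
                continue
            if len(table) == 0:
                continue
            feat_cols = [c for c in table.columns
                         if c not in ("recording_id", "subject_id", "dataset_tag",
                                      "age_months", "epoch_index")]
            res = predict_dap(model, table[feat_cols].to_numpy(dtype=float))
            out = table[["recording_id", "subject_id", "age_months", "epoch_index"]].copy()
            out["dap_months"] = res["dap_months"].to_numpy()
            frames.append(out)
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    # -- experiment 2 -------------------------------------------------------

    def exp2(self) -> dict:
        cfg = self.config
        physical = pd.read_csv(_require(self.out / "data" / "physical.csv", "generate"))
        charts = {}
        dap_tables = {}

        motor = self._motor_dap_table()
        charts["motor"] = build_chart(motor, "motor", n_boot=cfg.n_boot,
                                      n_boot_id=cfg.n_boot_id, seed=cfg.seed)
        dap_tables["motor"] = motor

        for modality, columns in PHYSICAL_COLUMNS.items():
            res = physical_dap(physical, columns, seed=cfg.seed,
                               n_folds=cfg.physical_folds, n_restarts=cfg.gpr_restarts)
            res.to_csv(self.out / f"dap_{modality}.csv", index=False)
            charts[modality] = build_chart(res, modality, n_boot=cfg.n_boot,
                                           n_boot_id=cfg.n_boot_id, seed=cfg.seed)
            dap_tables[modality] = res

        rows = []
        for modality, chart in charts.items():
            chart.monthly_table.to_csv(self.out / f"chart_{modality}_monthly.csv",
                                       index=False)
            self._plot_chart(chart, dap_tables[modality])
            for grouping, entry in chart.quality.items():
                rows.append({
                    "modality": modality, "grouping": grouping,
                    "r2": entry["r2"], "sigma": entry["sigma"],
                    "r2_ci_lo": entry["r2_ci"].lo, "r2_ci_hi": entry["r2_ci"].hi,
                    "sigma_ci_lo": entry["sigma_ci"].lo,
                    "sigma_ci_hi": entry["sigma_ci"].hi,
                    "n": entry["n"],
                })
        quality = pd.DataFrame(rows)
        quality.to_csv(self.out / "exp2_chart_quality.csv", index=False)
        self._charts = charts
        return {"modalities": list(charts),
                "quality": quality.round(4).to_dict("records")}

    # -- experiment 3 -------------------------------------------------------

    def exp3(self) -> dict:
        summary = {}
        fig, axes = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
        for modality in MODALITIES:
            path = (self.out / "dap_motor.csv" if modality == "motor"
                    else self.out / f"dap_{modality}.csv")
            _require(path, "exp2" if modality != "motor" else "dap")
            table = pd.read_csv(path)
            pairs = pair_deltas(table)
            if len(pairs) == 0:
                continue
            stats = delta_bin_stats(pairs)
            pairs.to_csv(self.out / f"exp3_pairs_{modality}.csv", index=False)
            stats.table.to_csv(self.out / f"exp3_bins_{modality}.csv", index=False)
            ok = stats.table[~stats.table["flagged"]]
            axes[0].plot(ok["bin_start"] + 0.5, ok["mean"], marker="o", label=modality)
            axes[1].plot(ok["bin_start"] + 0.5, ok["sd"], marker="o", label=modality)
            summary[modality] = {
                "n_pairs": int(len(pairs)),
                "monotone_means": stats.monotone_means,
                "short_interval_sd": float(ok[ok["bin_start"] < 4]["sd"].mean()),
                "long_interval_sd": float(ok[ok["bin_start"] >= 4]["sd"].mean()),
            }
        axes[0].set_ylabel("mean delta-DAP (months)")
        axes[1].set_ylabel("SD of delta-DAP (months)")
        axes[1].set_xlabel("measurement interval (months)")
        axes[0].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(self.out / "exp3_delta_dap.png", dpi=120)
        plt.close(fig)
        (self.out / "exp3_summary.json").write_text(json.dumps(summary, indent=2))
        return summary

    # -- plots --------------------------------------------------------------

    def _plot_chart(self, chart, dap_table: pd.DataFrame) -> None:
        fig, ax = plt.subplots(figsize=(6, 4.5))
        grid = np.linspace(dap_table["age_months"].min(),
                           dap_table["age_months"].max(), 200)
        lo, hi = chart.band(grid)
        ax.fill_between(grid, lo, hi, alpha=0.25, label="±1SD")
        ax.plot(grid, chart.fit(grid), lw=2, label="4PL fit")
        ax.scatter(dap_table["age_months"], dap_table["dap_months"], s=8, alpha=0.4)
        mm = chart.monthly_means()
        ax.scatter(mm["mean_age"], mm["mean"], s=45, zorder=3, label="monthly means")
        ax.set_xlabel("age (months)")
        ax.set_ylabel("DAP (months)")
        ax.set_title(f"{chart.modality}: R2 raw={chart.quality['raw']['r2']:.2f}, "
                     f"sigma={chart.sigma_band:.2f} mo")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(self.out / f"chart_{chart.modality}.png", dpi=120)
        plt.close(fig)

    def _plot_noise(self, noise) -> None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        diffs = noise.session_pairs["dap_diff"]
        axes[0].hist(diffs, bins=21)
        axes[0].set_xlabel("epoch DAP difference (months)")
        axes[0].set_title(f"sigma={noise.sigma_noise:.2f} mo, KS p={noise.ks_p:.2f}")
        axes[1].scatter(noise.session_pairs["age_months"], diffs.abs(), s=12)
        axes[1].set_xlabel("age (months)")
        axes[1].set_ylabel("|epoch DAP difference| (months)")
        axes[1].set_title(f"r={noise.age_corr_r:.2f}")
        fig.tight_layout()
        fig.savefig(self.out / "exp1_noise.png", dpi=120)
        plt.close(fig)


def run_experiment(name: str, config: RunConfig) -> dict:
    """Run one named experiment (or the whole pipeline) and return its report.

    ``exp1``: between-cohort replicability and epoch measurement noise;
    ``exp2``: DAP growth charts for motor / length / weight / HC / combined;
    ``exp3``: longitudinal delta-DAP tracking; ``all``: everything in order.
    Stage outputs live under ``config.out_dir``; a manifest records seeds.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    pipe = Pipeline(config)
    report: dict = {"experiment": name, "seed": config.seed,
                    "version": __version__}
    if name == "all":
        report["generate"] = pipe.stage_generate()
        report["features"] = pipe.stage_features()
        report["exp1"] = pipe.exp1()
        report["exp2"] = pipe.exp2()
        report["exp3"] = pipe.exp3()
    elif name == "exp1":
        report["exp1"] = pipe.exp1()
    elif name == "exp2":
        report["exp2"] = pipe.exp2()
    else:
        report["exp3"] = pipe.exp3()
    (Path(config.out_dir) / "manifest.json").write_text(
        json.dumps(report, indent=2, default=str))
    return report
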