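"""Developmental age prediction (DAP) with Gaussian-process regression.

DAP summarizes a measurement (a motor feature vector, or one or more
physical growth measures) as the expected age, in months, that generated
it.  It is implemented as the posterior mean of a GP regression of age on
the feature vector, with an RBF kernel plus a white-noise term; the GP
predictive SD quantifies measurement-level uncertainty.  Evaluation is
always subject-wise (leave-one-subject-out or grouped K-fold) so that no
infant contributes to both training and testing.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GroupKFold

N_RESTARTS: int = 5  # seeded hyperparameter-optimization restarts


@dataclasses.dataclass
class DAPDataset:
    """Feature matrix with per-row identity, the input to DAP fitting."""

    X: np.ndarray
    ages: np.ndarray
    subject_ids: np.ndarray
    recording_ids: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.ages = np.asarray(self.ages, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.recording_ids = np.asarray(self.recording_ids)
        n = len(self.ages)
        if not (self.X.shape[0] == n == len(self.subject_ids) == len(self.recording_ids)):
            raise ValueError("inconsistent row counts in DAPDataset")


@dataclasses.dataclass
class DAPModel:
    """Fitted GP age-regression model with its normalization and manifest."""

    gpr: GaussianProcessRegressor
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    recording_ids: np.ndarray
    subject_ids: np.ndarray
    seed: int
    model_tag: str

    @property
    def kernel_params(self) -> dict[str, float]:
        k = self.gpr.kernel_
        return {name: float(v) for name, v in k.get_params().items()
                if np.isscalar(v) and not isinstance(v, str)}

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.feature_mean) / self.feature_scale


def _manifest_tag(recording_ids, seed: int) -> str:
    h = hashlib.sha256(("|".join(map(str, recording_ids)) + f"#{seed}").encode())
    return h.hexdigest()[:12]


def fit_dap(ds: DAPDataset, seed: int = 0, n_restarts: int = N_RESTARTS,
            min_train: int = 10, feature_names: list[str] | None = None) -> DAPModel:
    """Fit the GP age regression by marginal-likelihood maximization.

    Features are standardized internally (structurally-zero columns — e.g.
    posture-movement cells that never occur — are kept at unit scale, since
    they carry no distance information).  A feature that is constant at a
    nonzero value across training indicates a degenerate input and raises,
    naming the offending dimensions.  The age target is centred and scaled
    by the GP; outputs are re-expressed in months.
    """
    X, ages = ds.X, ds.ages
    if X.shape[0] < min_train:
        raise ValueError(f"need >= {min_train} training recordings, got {X.shape[0]}")
    std = X.std(axis=0)
    mean = X.mean(axis=0)
    constant = std == 0
    degenerate = constant & (mean != 0)
    if degenerate.any() or constant.all():
        bad = np.flatnonzero(degenerate if degenerate.any() else constant)
        names = ([feature_names[i] for i in bad] if feature_names is not None
                 else bad.tolist())
        raise ValueError(f"degenerate constant feature dimensions: {names}")
    scale = np.where(constant, 1.0, std)
    mean = np.where(constant, 0.0, mean)
    Xs = (X - mean) / scale

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=np.sqrt(X.shape[1]), length_scale_bounds=(1e-2, 1e3))
              + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-6, 1e1)))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    gpr.fit(Xs, ages)
    return DAPModel(
        gpr=gpr, feature_mean=mean, feature_scale=scale,
        recording_ids=ds.recording_ids.copy(), subject_ids=ds.subject_ids.copy(),
        seed=seed, model_tag=_manifest_tag(ds.recording_ids, seed),
    )


def predict_dap(model: DAPModel, X: np.ndarray,
                recording_ids=None) -> pd.DataFrame:
    """Posterior predictive mean and SD (months) for each feature row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.feature_mean):
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({len(model.feature_mean)})")
    mu, sd = model.gpr.predict(model.transform(X), return_std=True)
    out = pd.DataFrame({
        "dap_months": mu,
        "predictive_sd_months": sd,
        "model_tag": model.model_tag,
    })
    if recording_ids is not None:
        out.insert(0, "recording_id", np.asarray(recording_ids))
    return out


def loso_cv(ds: DAPDataset, seed: int = 0, n_restarts: int = N_RESTARTS,
            n_folds: int | None = None) -> pd.DataFrame:
    """Subject-wise cross-validated DAP for every recording.

    With ``n_folds=None`` this is leave-one-subject-out: each recording is
    predicted by a model trained on all recordings of all *other* subjects.
    ``n_folds=k`` uses grouped K-fold instead (no subject crosses folds),
    which is the practical choice for cohorts with very many subjects.
    """
    subjects = np.unique(ds.subject_ids)
    if len(subjects) < 2:
        raise ValueError("subject-wise cross-validation needs >= 2 subjects")
    if n_folds is None:
        folds = [(ds.subject_ids != s, ds.subject_ids == s) for s in subjects]
    else:
        gkf = GroupKFold(n_splits=min(n_folds, len(subjects)))
        folds = []
        for tr, te in gkf.split(ds.X, ds.ages, groups=ds.subject_ids):
            tr_mask = np.zeros(len(ds.ages), dtype=bool); tr_mask[tr] = True
            te_mask = np.zeros(len(ds.ages), dtype=bool); te_mask[te] = True
            folds.append((tr_mask, te_mask))
    pieces = []
    for tr_mask, te_mask in folds:
        if set(ds.subject_ids[tr_mask]) & set(ds.subject_ids[te_mask]):
            raise AssertionError("subject leakage between train and test fold")
        model = fit_dap(DAPDataset(ds.X[tr_mask], ds.ages[tr_mask],
                                   ds.subject_ids[tr_mask], ds.recording_ids[tr_mask],
                                   tag=ds.tag),
                        seed=seed, n_restarts=n_restarts)
        res = predict_dap(model, ds.X[te_mask], recording_ids=ds.recording_ids[te_mask])
        res["subject_id"] = ds.subject_ids[te_mask]
        res["age_months"] = ds.ages[te_mask]
        pieces.append(res)
    out = pd.concat(pieces, ignore_index=True)
    order = pd.Index(ds.recording_ids, name="recording_id")
    return out.set_index("recording_id").loc[order].reset_index()


def cross_dataset_eval(train: DAPDataset, test: DAPDataset, seed: int = 0,
                       n_restarts: int = N_RESTARTS) -> pd.DataFrame:
    """Fit on one cohort, predict the other (one direction).

    Dataset tags and recording ids must be disjoint; run twice with the
    arguments swapped for both directions.
    """
    if train.tag == test.tag:
        raise ValueError(f"train and test cohorts share the dataset tag {train.tag!r}")
    overlap = set(train.recording_ids) & set(test.recording_ids)
    if overlap:
        raise ValueError(f"overlapping recording_ids between cohorts: {sorted(overlap)[:5]}")
    model = fit_dap(train, seed=seed, n_restarts=n_restarts)
    res = predict_dap(model, test.X, recording_ids=test.recording_ids)
    res["subject_id"] = test.subject_ids
    res["age_months"] = test.ages
    res["train_tag"] = train.tag
    return res


def physical_dap(table: pd.DataFrame, columns: list[str], seed: int = 0,
                 n_folds: int | None = 5, n_restarts: int = N_RESTARTS) -> pd.DataFrame:
    """Subject-wise cross-validated DAP from physical growth measures.

    ``columns`` selects the feature set: one of length/weight/HC alone or
    all three combined.  Each measurement (row) gets its own DAP.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing physical columns: {missing}")
    ds = DAPDataset(
        X=table[columns].to_numpy(dtype=float),
        ages=table["age_months"].to_numpy(dtype=float),
        subject_ids=table["subject_id"].to_numpy(),
        recording_ids=np.array([f"meas{i:06d}" for i in range(len(table))]),
        tag="+".join(columns),
    )
    return loso_cv(ds, seed=seed, n_restarts=n_restarts, n_folds=n_folds)


def evaluate_dap(results: pd.DataFrame) -> dict[str, float]:
    """RMSE, DAP-on-age OLS slope, and R^2 of cross-validated DAP scores."""
    age = results["age_months"].to_numpy()
    dap = results["dap_months"].to_numpy()
    err = dap - age
    slope, intercept = np.polyfit(age, dap, 1)
    ss_res = float(np.sum((dap - age) ** 2))
    ss_tot = float(np.sum((age - age.mean()) ** 2))
    return {
        "rmse_months": float(np.sqrt(np.mean(err ** 2))),
        "slope": float(slope),
        "intercept": float(intercept),
        "r2_vs_age": 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        "n": int(len(results)),
    }
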