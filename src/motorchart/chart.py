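"""Growth-chart construction: 4-parameter logistic fits of DAP vs age,
goodness-of-fit at raw / monthly-mean / ID-controlled levels, random-intercept
serial-measurement correction, and bootstrap confidence intervals.

The mean model is the four-parameter logistic (4PL) sigmoid

    f(x) = L + (U - L) / (1 + exp(-k (x - x0)))

with lower/upper asymptotes ``L``/``U`` (months), midpoint ``x0`` (months)
and slope ``k`` (1/months).  Chart sigma is the root-mean-square residual in
months (the ±1SD band half-width), not a ddof-corrected SD, so raw and
grouped definitions stay consistent.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize
import statsmodels.api as sm

logger = logging.getLogger("motorchart")


@dataclasses.dataclass
class SigmoidParams:
    L: float
    U: float
    x0: float
    k: float
    converged: bool = True
    sse: float = float("nan")

    def __call__(self, x):
        return sigmoid(np.asarray(x, dtype=float), self.L, self.U, self.x0, self.k)

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.U, self.x0, self.k])


def sigmoid(x, L, U, x0, k):
    z = np.clip(-k * (np.asarray(x, dtype=float) - x0), -500.0, 500.0)
    return L + (U - L) / (1.0 + np.exp(z))


def _normalize(theta: np.ndarray) -> np.ndarray:
    """Canonical parameterization: U >= L (swap asymptotes and negate k)."""
    L, U, x0, k = theta
    if U < L:
        return np.array([U, L, x0, -k])
    return theta


def fit_sigmoid(ages, values, init_strategy: str = "data",
                x0_init: float | None = None) -> SigmoidParams:
    """Least-squares 4PL fit with data-driven multi-start initialization.

    Starts from L = min(values), U = max(values), x0 = median(age) and slope
    k in {0.2, 0.5, 1} (sign taken from the data trend); the best-SSE
    solution is returned with a convergence flag.  Constant values yield the
    degenerate flat fit (U ~ L) without error.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 5:
        raise ValueError("sigmoid fit needs >= 5 points")
    if np.ptp(ages) == 0:
        raise ValueError("sigmoid fit needs varying ages")

    if init_strategy == "data":
        L0, U0 = float(values.min()), float(values.max())
        xm = float(np.median(ages)) if x0_init is None else x0_init
    else:
        raise ValueError(f"unknown init strategy {init_strategy!r}")
    trend = np.sign(np.polyfit(ages, values, 1)[0]) or 1.0

    def resid(theta):
        return sigmoid(ages, *theta) - values

    best = None
    diagnostics = []
    for k0 in (0.2, 0.5, 1.0):
        start = np.array([L0, U0, xm, trend * k0])
        try:
            sol = optimize.least_squares(resid, start, method="lm", max_nfev=5000)
        except Exception as exc:  # pragma: no cover - LM rarely raises
            diagnostics.append(f"start k={k0}: {exc}")
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, sol)
    if best is None:
        raise RuntimeError("all sigmoid starts failed: " + "; ".join(diagnostics))
    sse, sol = best
    theta = _normalize(sol.x)
    return SigmoidParams(*map(float, theta), converged=bool(sol.success), sse=sse)


def refit_sigmoid(ages, values, warm: SigmoidParams) -> SigmoidParams:
    """Single-start refit from an existing solution (bootstrap resamples)."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)

    def resid(theta):
        return sigmoid(ages, *theta) - values

    sol = optimize.least_squares(resid, warm.as_array(), method="lm", max_nfev=2000)
    theta = _normalize(sol.x)
    return SigmoidParams(*map(float, theta), converged=bool(sol.success),
                         sse=float(np.sum(sol.fun ** 2)))


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def _monthly_groups(ages: np.ndarray) -> np.ndarray:
    return np.floor(ages).astype(int)


def goodness_of_fit(fit: SigmoidParams, ages, values, grouping: str = "raw",
                    subject_ids=None) -> dict[str, float]:
    """R^2 and sigma (RMS residual, months) of a fitted chart model.

    Groupings: ``raw`` uses every measurement; ``monthly_means`` evaluates
    bin-mean values against the model at bin-mean ages; ``id_controlled``
    removes estimated per-subject random intercepts from the raw residuals
    first (R^2 is then computed against the raw total sum of squares, so
    removing subject offsets can only tighten it).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if grouping == "raw":
        resid = values - fit(ages)
        ss_tot = float(np.sum((values - values.mean()) ** 2))
    elif grouping == "monthly_means":
        g = _monthly_groups(ages)
        bins = np.unique(g)
        mean_age = np.array([ages[g == b].mean() for b in bins])
        mean_val = np.array([values[g == b].mean() for b in bins])
        resid = mean_val - fit(mean_age)
        ss_tot = float(np.sum((mean_val - mean_val.mean()) ** 2))
    elif grouping == "id_controlled":
        if subject_ids is None:
            raise ValueError("id_controlled grouping needs subject_ids")
        corr = lme_correction(ages, values, subject_ids, fit)
        resid = corr.corrected_residuals
        ss_tot = float(np.sum((values - values.mean()) ** 2))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    ss_res = float(np.sum(resid ** 2))
    flagged = ss_tot == 0
    r2 = 0.0 if flagged else 1.0 - ss_res / ss_tot
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    return {"r2": float(r2), "sigma": sigma, "n": int(len(resid)),
            "zero_variance": bool(flagged)}


# ---------------------------------------------------------------------------
# Serial-measurement (random intercept) correction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LMECorrection:
    intercepts: dict               # subject -> estimated offset b_i (months)
    corrected_residuals: np.ndarray
    intercept_var: float
    residual_var: float
    sigma_idcontrolled: float
    used_lme: bool = True


def lme_correction(ages, values, subject_ids, fit: SigmoidParams) -> LMECorrection:
    """Two-stage serial-measurement correction.

    Stage 1: residuals ``r_ij = value_ij - f(age_ij)`` from the fitted mean
    curve.  Stage 2: random-intercept model ``r_ij = b_i + e_ij`` fitted by
    REML; the corrected residuals are ``e_ij = r_ij - b_i`` and
    ``sigma_idcontrolled = RMS(e_ij)``.  If no subject has repeat
    measurements the intercepts are undefined and raw residuals are
    returned with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    subject_ids = np.asarray(subject_ids)
    r = values - fit(ages)
    _, counts = np.unique(subject_ids, return_counts=True)
    if (counts < 2).all():
        logger.warning("all subjects have a single measurement; "
                       "random intercepts undefined, returning raw residuals")
        return LMECorrection(intercepts={}, corrected_residuals=r,
                             intercept_var=float("nan"), residual_var=float(np.var(r)),
                             sigma_idcontrolled=float(np.sqrt(np.mean(r ** 2))),
                             used_lme=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(r, np.ones((len(r), 1)), groups=subject_ids)
            res = model.fit(reml=True)
        intercepts = {s: float(re.iloc[0]) for s, re in res.random_effects.items()}
        intercept_var = float(np.asarray(res.cov_re)[0, 0])
        residual_var = float(res.scale)
    except (np.linalg.LinAlgError, ValueError):
        # degenerate covariance (e.g. residuals numerically zero): fall back
        # to unshrunken per-subject means
        means = pd.Series(r).groupby(pd.Series(subject_ids)).mean()
        intercepts = means.to_dict()
        intercept_var = float(means.var(ddof=1)) if len(means) > 1 else 0.0
        residual_var = float(
            np.var(r - np.array([intercepts[s] for s in subject_ids])))
        b = np.array([intercepts[s] for s in subject_ids])
        e = r - b
        return LMECorrection(intercepts=intercepts, corrected_residuals=e,
                             intercept_var=intercept_var, residual_var=residual_var,
                             sigma_idcontrolled=float(np.sqrt(np.mean(e ** 2))))
    b = np.array([intercepts[s] for s in subject_ids])
    e = r - b
    return LMECorrection(
        intercepts=intercepts,
        corrected_residuals=e,
        intercept_var=intercept_var,
        residual_var=residual_var,
        sigma_idcontrolled=float(np.sqrt(np.mean(e ** 2))),
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BootstrapCI:
    lo: float
    hi: float
    n_boot: int
    n_redrawn: int = 0

    def __iter__(self):
        return iter((self.lo, self.hi))

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def overlaps(self, other: "BootstrapCI") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


def bootstrap_ci(metric_fn, data: pd.DataFrame, n_boot: int = 10000,
                 unit: str = "recording", seed: int = 0,
                 group_col: str = "subject_id", max_redraw: int = 1000) -> BootstrapCI:
    """Percentile 95% CI of ``metric_fn(resampled data)``.

    Resampling is with replacement at the configured unit: individual rows
    (``recording``) or whole subjects (``subject``, keeping all rows of each
    drawn subject).  Resamples on which the metric is undefined (NaN or an
    exception) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    if unit == "subject":
        groups = data[group_col].to_numpy()
        uniq = np.unique(groups)
        index_of = {g: np.flatnonzero(groups == g) for g in uniq}
    elif unit != "recording":
        raise ValueError(f"unknown bootstrap unit {unit!r}")

    stats = np.empty(n_boot)
    redrawn = 0
    i = 0
    while i < n_boot:
        if unit == "recording":
            take = rng.integers(0, len(data), size=len(data))
        else:
            drawn = rng.choice(uniq, size=len(uniq), replace=True)
            take = np.concatenate([index_of[g] for g in drawn])
        try:
            val = metric_fn(data.iloc[take])
        except Exception:
            val = float("nan")
        if np.isnan(val):
            redrawn += 1
            if redrawn > max_redraw:
                raise RuntimeError("bootstrap metric undefined on too many resamples")
            continue
        stats[i] = val
        i += 1
    if redrawn:
        logger.info("bootstrap redrew %d resamples with undefined metric", redrawn)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return BootstrapCI(float(lo), float(hi), n_boot=n_boot, n_redrawn=redrawn)


def _bootstrap_multi(metric_fn, data: pd.DataFrame, n_boot: int,
                     unit: str, seed: int,
                     group_col: str = "subject_id",
                     max_redraw: int = 1000,
                     center: dict[str, float] | None = None) -> dict[str, BootstrapCI]:
    """Like :func:`bootstrap_ci` for a dict-valued metric (one resample pass).

    When ``center`` supplies the full-data point estimates, the interval is
    recentred by the bootstrap bias (mean of resamples minus point estimate)
    so that upward-biased resampling of grouped metrics still yields an
    interval containing the point estimate.
    """
    rng = np.random.default_rng(seed)
    if unit == "subject":
        groups = data[group_col].to_numpy()
        uniq = np.unique(groups)
        index_of = {g: np.flatnonzero(groups == g) for g in uniq}
    collected: dict[str, list[float]] = {}
    redrawn = 0
    i = 0
    while i < n_boot:
        if unit == "recording":
            take = rng.integers(0, len(data), size=len(data))
        else:
            drawn = rng.choice(uniq, size=len(uniq), replace=True)
            take = np.concatenate([index_of[g] for g in drawn])
        try:
            vals = metric_fn(data.iloc[take])
        except Exception:
            vals = None
        if vals is None or any(np.isnan(v) for v in vals.values()):
            redrawn += 1
            if redrawn > max_redraw:
                raise RuntimeError("bootstrap metric undefined on too many resamples")
            continue
        for key, v in vals.items():
            collected.setdefault(key, []).append(float(v))
        i += 1
    out = {}
    for key, arr in collected.items():
        lo, hi = np.percentile(arr, [2.5, 97.5])
        if center is not None and key in center:
            bias = float(np.mean(arr)) - center[key]
            lo, hi = lo - bias, hi - bias
        out[key] = BootstrapCI(float(lo), float(hi), n_boot=n_boot, n_redrawn=redrawn)
    return out


def sigmoid_param_cis(table: pd.DataFrame, value_col: str = "dap_months",
                      n_boot: int = 1000, seed: int = 0,
                      warm: SigmoidParams | None = None) -> dict[str, BootstrapCI]:
    """Bootstrap 95% CIs of the four 4PL parameters (recording-level resampling).

    Resample refits are warm-started from the full-data solution.
    """
    if warm is None:
        warm = fit_sigmoid(table["age_months"], table[value_col])
    names = ("L", "U", "x0", "k")

    def resample_params(t: pd.DataFrame) -> dict[str, float]:
        refit = refit_sigmoid(t["age_months"], t[value_col], warm)
        return dict(zip(names, refit.as_array()))

    return _bootstrap_multi(resample_params, table, n_boot=n_boot,
                            unit="recording", seed=seed)


# ---------------------------------------------------------------------------
# Chart bundle
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ChartBundle:
    modality: str
    fit: SigmoidParams
    quality: dict[str, dict]          # grouping -> {r2, sigma, ci...}
    param_ci: dict[str, BootstrapCI]  # L/U/x0/k bootstrap CIs
    monthly_table: pd.DataFrame       # bin, mean, sd, n
    sigma_band: float                 # ±1SD band half-width (sigma_raw)
    n: int

    def band(self, x):
        f = self.fit(x)
        return f - self.sigma_band, f + self.sigma_band

    def monthly_means(self) -> pd.DataFrame:
        return self.monthly_table[self.monthly_table["n"] > 0]


def build_chart(values_table: pd.DataFrame, modality_tag: str,
                value_col: str = "dap_months", n_boot: int = 1000,
                n_boot_id: int = 200, seed: int = 0,
                min_points: int = 15, min_bins: int = 6) -> ChartBundle:
    """Fit a growth chart of DAP (or any value) against age.

    Requires >= ``min_points`` measurements spanning >= ``min_bins`` monthly
    bins.  Produces the 4PL fit, R^2/sigma at raw, monthly-mean, and
    ID-controlled levels with bootstrap CIs, a monthly mean/SD table, and
    the ±1SD band half-width.
    """
    ages = values_table["age_months"].to_numpy(dtype=float)
    values = values_table[value_col].to_numpy(dtype=float)
    subjects = values_table["subject_id"].to_numpy() if "subject_id" in values_table else None
    bins = np.unique(_monthly_groups(ages))
    if len(values) < min_points or len(bins) < min_bins:
        raise ValueError(
            f"insufficient span for chart {modality_tag!r}: "
            f"{len(values)} points over {len(bins)} monthly bins "
            f"(need >= {min_points} / {min_bins})")
    fit = fit_sigmoid(ages, values)

    def resample_metrics(table: pd.DataFrame, grouping: str) -> dict[str, float]:
        a = table["age_months"].to_numpy(dtype=float)
        v = table[value_col].to_numpy(dtype=float)
        refit = refit_sigmoid(a, v, fit)
        sid = table["subject_id"] if grouping == "id_controlled" else None
        gof = goodness_of_fit(refit, a, v, grouping, subject_ids=sid)
        return {"r2": gof["r2"], "sigma": gof["sigma"]}

    quality: dict[str, dict] = {}
    for grouping, unit, nb in (("raw", "recording", n_boot),
                               ("monthly_means", "recording", n_boot),
                               ("id_controlled", "subject", n_boot_id)):
        if grouping == "id_controlled" and subjects is None:
            continue
        entry = dict(goodness_of_fit(fit, ages, values, grouping, subject_ids=subjects))
        cis = _bootstrap_multi(lambda t, g=grouping: resample_metrics(t, g),
                               values_table, n_boot=max(nb, 100), unit=unit, seed=seed,
                               center={"r2": entry["r2"], "sigma": entry["sigma"]})
        entry["r2_ci"] = cis["r2"]
        entry["sigma_ci"] = cis["sigma"]
        quality[grouping] = entry

    param_ci = sigmoid_param_cis(values_table, value_col=value_col,
                                 n_boot=max(n_boot, 100), seed=seed + 1, warm=fit)

    g = _monthly_groups(ages)
    rows = []
    for b in range(int(bins.min()), int(bins.max()) + 1):
        sel = g == b
        rows.append({
            "bin_start": b,
            "n": int(sel.sum()),
            "mean": float(values[sel].mean()) if sel.any() else float("nan"),
            "sd": float(values[sel].std(ddof=0)) if sel.any() else float("nan"),
            "mean_age": float(ages[sel].mean()) if sel.any() else float("nan"),
        })
    monthly = pd.DataFrame(rows)
    return ChartBundle(
        modality=modality_tag, fit=fit, quality=quality, param_ci=param_ci,
        monthly_table=monthly, sigma_band=quality["raw"]["sigma"], n=len(values),
    )
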