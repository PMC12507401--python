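"""Healthy-lifestyle scoring and survival analyses.

The healthy lifestyle index (HLI) counts four behaviours — regular
exercise, no current smoking, no regular drinking, and a healthy diet
(top two quintiles of the 0-45 food-pagoda diet score, or fiber intake
above 20 g/day) — at baseline and at the most recent survey; HLI <= 2 is a
"low" score, and the baseline/recent pair defines long-term adherence
groups (low-low .. high-high).

Residual life expectancy is the area under the all-cause survival curve
from age 45 to 100, conditional on being alive at 45, from a parametric
right-censored MLE (exponential, Weibull or Gompertz; Gompertz is the
default for adult mortality).  Incident type-2 diabetes with death as a
competing event is summarised by Aalen-Johansen cumulative incidence
functions, a permutation contrast of the CIFs between groups, and a
cause-specific Cox model (competing events censored, Efron ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import integrate, optimize

from .io import ConvergenceError, ValidationError

FIBER_THRESHOLD_G_PER_DAY = 20.0
HLI_LOW_MAX = 2  # low score iff HLI <= 2
ADHERENCE_LEVELS = ("low-low", "low-high", "high-low", "high-high")


# ---------------------------------------------------------------- lifestyle


def _healthy_diet(
    meta: pd.DataFrame, wave: str, chfp: pd.Series | None, fiber: pd.Series | None
) -> pd.Series:
    col = f"healthy_diet_{wave}"
    if chfp is None and fiber is None:
        return meta[col].astype(bool)
    healthy = pd.Series(False, index=meta.index)
    if chfp is not None:
        cutoff = chfp.quantile(0.6)  # top two quintiles
        healthy |= chfp >= cutoff
    if fiber is not None:
        healthy |= fiber > FIBER_THRESHOLD_G_PER_DAY
    return healthy


def score_lifestyle(
    metadata: pd.DataFrame,
    chfp_scores: pd.Series | None = None,
    fiber_g_per_day: pd.Series | None = None,
) -> pd.DataFrame:
    """HLI (0-4) at both waves, low/high groups, and adherence category.

    When a diet-score table or fiber intake is supplied, the healthy-diet
    criterion is recomputed from it (top-two-quintile diet score within the
    analysis population, or fiber > 20 g/day); otherwise the boolean
    healthy-diet flags in the metadata are used as-is.
    """
    needed = [
        f"{b}_{w}"
        for b in ("exercise", "smoking", "drinking", "healthy_diet")
        for w in ("baseline", "recent")
    ]
    missing = [c for c in needed if c not in metadata.columns]
    if missing:
        raise ValidationError(f"missing behaviour fields: {missing}")
    out = pd.DataFrame(index=metadata.index)
    for wave in ("baseline", "recent"):
        diet = _healthy_diet(metadata, wave, chfp_scores, fiber_g_per_day)
        hli = (
            metadata[f"exercise_{wave}"].astype(int)
            + (~metadata[f"smoking_{wave}"].astype(bool)).astype(int)
            + (~metadata[f"drinking_{wave}"].astype(bool)).astype(int)
            + diet.astype(int)
        )
        out[f"hli_{wave}"] = hli
        out[f"group_{wave}"] = np.where(hli <= HLI_LOW_MAX, "low", "high")
    out["adherence"] = out["group_baseline"] + "-" + out["group_recent"]
    return out


def hli_microbial_age_regression(
    scores: pd.DataFrame,
    ma: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=("age", "sex", "bmi", "education"),
) -> dict:
    """OLS of microbial age on the recent HLI and on adherence categories.

    Returns the per-point HLI slope and, with the low-low group as the
    reference, one contrast per adherence category, each with a 95% CI.
    """
    idx = ma.index.intersection(scores.index).intersection(metadata.index)
    y = ma.loc[idx, "microbial_age"].to_numpy(dtype=float)
    meta = metadata.loc[idx]

    def covariate_frame() -> pd.DataFrame:
        X = pd.DataFrame(index=idx)
        if "age" in covariates:
            X["age_years"] = meta["age_years"].astype(float)
        if "sex" in covariates and meta["sex"].nunique() > 1:
            X["sex_female"] = (meta["sex"] == "female").astype(float)
        if "bmi" in covariates:
            X["bmi"] = meta["bmi"].astype(float)
        if "education" in covariates:
            X["education"] = meta["education"].astype(float)
        return X

    hli = scores.loc[idx, "hli_recent"].astype(float)
    if hli.nunique() < 2:
        raise ValidationError("HLI has no variation")
    X = covariate_frame()
    X.insert(0, "hli", hli)
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    ci = fit.conf_int().loc["hli"]
    result = {
        "hli_per_point": {
            "beta": float(fit.params["hli"]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "p": float(fit.pvalues["hli"]),
            "n": int(fit.nobs),
        }
    }

    adherence = scores.loc[idx, "adherence"]
    if (adherence == "low-low").sum() == 0:
        raise ValidationError("reference adherence group 'low-low' is empty")
    X = covariate_frame()
    for level in ADHERENCE_LEVELS[1:]:
        X[f"adh_{level}"] = (adherence == level).astype(float)
    fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    for level in ADHERENCE_LEVELS[1:]:
        name = f"adh_{level}"
        if (adherence == level).sum() == 0:
            continue
        ci = fit.conf_int().loc[name]
        result[level] = {
            "beta": float(fit.params[name]),
            "ci_low": float(ci[0]),
            "ci_high": float(ci[1]),
            "p": float(fit.pvalues[name]),
            "n": int((adherence == level).sum()),
        }
    return result


# ------------------------------------------------------- parametric survival


@dataclass
class SurvivalFit:
    family: str
    params: dict[str, float]
    se: dict[str, float]
    log_likelihood: float

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return np.exp(-self.params["rate"] * t)
        if self.family == "weibull":
            k, lam = self.params["shape"], self.params["scale"]
            return np.exp(-((t / lam) ** k))
        if self.family == "gompertz":
            a, b = self.params["rate"], self.params["shape"]
            return np.exp(-a / b * (np.exp(b * t) - 1.0))
        raise ValidationError(f"unknown family {self.family!r}")


_FAMILY_PARAMS = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("rate", "shape"),
}


def _neg_loglik(family: str, logtheta: np.ndarray, t: np.ndarray, e: np.ndarray):
    th = np.exp(logtheta)
    if family == "exponential":
        (lam,) = th
        return -(e * np.log(lam) - lam * t).sum()
    if family == "weibull":
        k, lam = th
        z = t / lam
        logh = np.log(k / lam) + (k - 1) * np.log(np.maximum(z, 1e-300))
        return -(e * logh - z**k).sum()
    if family == "gompertz":
        a, b = th
        logh = np.log(a) + b * t
        H = a / b * (np.exp(b * t) - 1.0)
        return -(e * logh - H).sum()
    raise ValidationError(f"unknown family {family!r}")


def fit_parametric_survival(
    times,
    events,
    family: str = "gompertz",
    condition_age: float = 45.0,
    horizon: float = 100.0,
) -> tuple[SurvivalFit, float]:
    """Right-censored MLE plus conditional residual life expectancy.

    ``times`` are ages at death or censoring; ``events`` flags deaths.
    Returns the fit and RLE = integral_{c}^{h} S(t)/S(c) dt (closed form for
    the exponential, adaptive quadrature otherwise).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool).astype(float)
    if family not in _FAMILY_PARAMS:
        raise ValidationError(f"unknown family {family!r}")
    if e.sum() == 0:
        raise ValidationError("no events; survival fit undefined")
    if np.any(t <= 0):
        raise ValidationError("times must be positive")

    names = _FAMILY_PARAMS[family]
    if family == "exponential":
        lam = e.sum() / t.sum()  # closed-form MLE
        theta = np.array([lam])
        se_lam = lam / math.sqrt(e.sum())
        fitted = SurvivalFit(
            family, {"rate": lam}, {"rate": se_lam}, -_neg_loglik(family, np.log(theta), t, e)
        )
    else:
        x0 = np.log(np.array([e.sum() / t.sum(), 0.05][: len(names)]))
        if family == "weibull":
            x0 = np.log(np.array([1.0, t.mean()]))
        res = optimize.minimize(
            lambda x: _neg_loglik(family, x, t, e), x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
        )
        if not res.success:
            raise ConvergenceError(f"survival MLE did not converge: {res.message}")
        th = np.exp(res.x)
        # numerical SEs on the natural scale via central-difference Hessian
        se = _mle_se(lambda x: _neg_loglik(family, np.log(np.maximum(x, 1e-12)), t, e), th)
        fitted = SurvivalFit(
            family,
            dict(zip(names, map(float, th))),
            dict(zip(names, map(float, se))),
            -float(res.fun),
        )

    rle = residual_life_expectancy(fitted, condition_age, horizon)
    return fitted, rle


def _mle_se(nll, theta: np.ndarray) -> np.ndarray:
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-5 * np.maximum(np.abs(theta), 1e-3)
    for i in range(k):
        for j in range(k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = (nll(tpp) - nll(tpm) - nll(tmp) + nll(tmm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


def residual_life_expectancy(
    fit: SurvivalFit, condition_age: float = 45.0, horizon: float = 100.0
) -> float:
    """Conditional expected years lived between ``condition_age`` and
    ``horizon``: integral of S(t)/S(condition_age)."""
    if fit.family == "exponential":
        lam = fit.params["rate"]
        return float((1.0 - math.exp(-lam * (horizon - condition_age))) / lam)
    s_c = float(fit.survival(condition_age))
    val, _err = integrate.quad(
        lambda u: float(fit.survival(u)) / s_c, condition_age, horizon, limit=200
    )
    return float(val)


# ----------------------------------------------------------- competing risks


@dataclass
class CompetingRiskResult:
    cif: pd.DataFrame  # columns: time, overall_survival, cif_<cause>...
    cox: pd.DataFrame | None = None  # per-covariate log-HR, se, CI, p
    gray_style_p: float | None = None
    cause: str = "t2dm"
    extras: dict = field(default_factory=dict)


def aalen_johansen(times, event_codes, causes=("t2dm", "death")) -> pd.DataFrame:
    """Aalen-Johansen cumulative incidence functions for each cause.

    ``event_codes`` uses "none" for censoring.  At every event time t_i,
    CIF_k jumps by S(t_i-) d_k / n_i with S the all-cause Kaplan-Meier.
    By construction S(t) + sum_k CIF_k(t) = 1 at every event time.
    """
    t = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=object)
    order = np.argsort(t, kind="stable")
    t, codes = t[order], codes[order]
    event_times = np.unique(t[codes != "none"])
    n = len(t)
    rows = []
    surv = 1.0
    cif = dict.fromkeys(causes, 0.0)
    for et in event_times:
        at_risk = int((t >= et).sum())
        d_total = int(((t == et) & (codes != "none")).sum())
        for cause in causes:
            d_k = int(((t == et) & (codes == cause)).sum())
            cif[cause] += surv * d_k / at_risk
        surv *= 1.0 - d_total / at_risk
        rows.append(
            {"time": et, "overall_survival": surv, **{f"cif_{c}": cif[c] for c in causes}}
        )
    return pd.DataFrame(rows)


def _cif_contrast_stat(times, codes, group, cause: str) -> float:
    """Integrated absolute difference between the two groups' cause CIFs."""
    groups = np.unique(group)
    grid = np.unique(np.asarray(times, dtype=float))
    curves = []
    for g in groups[:2]:
        m = group == g
        cf = aalen_johansen(np.asarray(times)[m], np.asarray(codes, dtype=object)[m])
        col = cf[f"cif_{cause}"].to_numpy()
        # step-function evaluation on the common grid
        vals = np.zeros(len(grid))
        if len(cf):
            idx = np.searchsorted(cf["time"].to_numpy(), grid, side="right") - 1
            vals = np.where(idx >= 0, col[np.maximum(idx, 0)], 0.0)
        curves.append(vals)
    if len(grid) < 2:
        return float(np.abs(curves[0] - curves[1]).max())
    return float(np.trapezoid(np.abs(curves[0] - curves[1]), grid))


def competing_risk_analysis(
    df: pd.DataFrame,
    covariates: list[str],
    cause: str = "t2dm",
    group_col: str | None = None,
    n_permutations: int = 499,
    seed: int | None = None,
    time_col: str = "followup_months",
    event_col: str = "event",
) -> CompetingRiskResult:
    """CIFs, a permutation CIF contrast, and a cause-specific Cox model.

    The Cox model treats the competing event as censoring for the cause of
    interest (cause-specific hazard), fitted by partial likelihood with
    Efron tie handling.  The group contrast permutes the group label and
    compares integrated CIF differences (add-one p).
    """
    times = df[time_col].to_numpy(dtype=float)
    codes = df[event_col].to_numpy(dtype=object)
    if (codes == cause).sum() < 1:
        raise ValidationError(f"no events of cause {cause!r}")
    cif = aalen_johansen(times, codes)

    gray_p = None
    if group_col is not None:
        group = df[group_col].to_numpy(dtype=object)
        if len(np.unique(group)) != 2:
            raise ValidationError("group contrast requires exactly two groups")
        obs = _cif_contrast_stat(times, codes, group, cause)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            gp = group[rng.permutation(len(group))]
            if _cif_contrast_stat(times, codes, gp, cause) >= obs - 1e-12:
                exceed += 1
        gray_p = (1.0 + exceed) / (n_permutations + 1.0)

    cox = None
    if covariates:
        work = df[covariates].astype(float).copy()
        work["duration"] = times
        work["observed"] = (codes == cause).astype(int)
        cph = CoxPHFitter()
        try:
            cph.fit(work, duration_col="duration", event_col="observed")
        except Exception as exc:  # lifelines raises its own convergence errors
            raise ConvergenceError(
                f"cause-specific Cox did not converge: {exc}"
            ) from exc
        summ = cph.summary
        cox = pd.DataFrame(
            {
                "covariate": summ.index,
                "log_hr": summ["coef"].to_numpy(),
                "se": summ["se(coef)"].to_numpy(),
                "ci_low": summ["coef lower 95%"].to_numpy(),
                "ci_high": summ["coef upper 95%"].to_numpy(),
                "p": summ["p"].to_numpy(),
            }
        ).reset_index(drop=True)

    return CompetingRiskResult(cif=cif, cox=cox, gray_style_p=gray_p, cause=cause)
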