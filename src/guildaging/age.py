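"""Sex-specific random-forest microbial age and its downstream contrasts.

Microbial age is chronological age predicted from age-associated guild
abundances by a random-forest regression (mtry = floor(p/3), 1000 trees).
For the healthy training samples the prediction is taken out-of-bag — an
in-bag prediction would trivially track chronological age and destroy the
deviation construct — while diseased samples are scored by applying the
fitted forest.  A sex-specific OLS line of microbial age on chronological
age over the healthy samples defines the average healthy microbial age;
samples above the line (deviation > 0) are labelled "old", all others
"young".  The per-year deviation feeds the prospective hazard models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .io import ValidationError

MODEL1_COVARIATES = ("age_years",)
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "bmi", "energy_kcal", "education",
    "exercise_recent", "smoking_recent", "drinking_recent",
)
MEDICATION_COLUMNS = ("antihypertensive", "hypoglycemic", "lipid_lowering")
EXCLUDE_USER_COLUMNS = ("analgesic_user", "hormone_user")


def select_age_features(results: pd.DataFrame, sex: str, alpha: float = 0.05) -> list[str]:
    """Features with raw p strictly below alpha in the given sex stratum.

    Deliberately uncorrected: the forest is meant to pool weak signals, so
    the inclusive p < 0.05 screen is used rather than the FDR-adjusted set.
    """
    sub = results[(results["stratum"] == sex) & (results["p"] < alpha)]
    feats = sorted(sub["feature"].unique())
    if len(feats) < 2:
        raise ValidationError(
            f"only {len(feats)} feature(s) pass p < {alpha} for {sex!r}; "
            "increase alpha or provide more features"
        )
    return feats


@dataclass
class MicrobialAgeModel:
    sex: str
    features: list[str]
    forest: RandomForestRegressor
    training_ids: list[str]
    oob_prediction: pd.Series
    cv_curve: pd.DataFrame | None = field(default=None)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        """Apply the forest to new samples; refuses training samples, whose
        microbial age must come from the out-of-bag predictions."""
        overlap = set(X.index) & set(self.training_ids)
        if overlap:
            raise ValidationError(
                f"sample {sorted(overlap)[0]!r} was used in training; "
                "use its out-of-bag prediction instead"
            )
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise ValidationError(f"missing features in applied set: {missing}")
        return pd.Series(
            self.forest.predict(X[self.features].to_numpy()), index=X.index
        )


def fit_microbial_age(
    features: pd.DataFrame,
    ages: pd.Series,
    sex: str = "all",
    ntree: int = 1000,
    mtry: int | None = None,
    cv_folds: int = 10,
    seed: int | None = None,
    cv_curve: bool = False,
    cv_ntree: int = 200,
) -> MicrobialAgeModel:
    """Random-forest regression of chronological age on guild features.

    mtry defaults to max(1, floor(p/3)).  Training-sample microbial age is
    the out-of-bag prediction.  With ``cv_curve`` a k-fold cross-validated
    MSE curve over decreasing feature counts (ranked by importance) is
    attached for reporting; it does not prune the feature set.
    """
    if len(features) < 20:
        raise ValidationError("need at least 20 training samples")
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature values")
    y = np.asarray(ages, dtype=float)
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, p // 3)
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        min_samples_leaf=5,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    oob = pd.Series(rf.oob_prediction_, index=features.index)

    curve = None
    if cv_curve:
        order = np.argsort(rf.feature_importances_)[::-1]
        counts, mses = [], []
        k = p
        while k >= 1:
            cols = order[:k]
            mse_folds = []
            splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
            for tr, te in splitter.split(X):
                sub = RandomForestRegressor(
                    n_estimators=cv_ntree,
                    max_features=max(1, k // 3),
                    min_samples_leaf=5,
                    random_state=seed,
                    n_jobs=1,
                )
                sub.fit(X[np.ix_(tr, cols)], y[tr])
                pred = sub.predict(X[np.ix_(te, cols)])
                mse_folds.append(float(np.mean((pred - y[te]) ** 2)))
            counts.append(k)
            mses.append(float(np.mean(mse_folds)))
            k = k // 2 if k > 1 else 0
        curve = pd.DataFrame({"n_features": counts, "cv_mse": mses})

    return MicrobialAgeModel(
        sex=sex,
        features=list(features.columns),
        forest=rf,
        training_ids=list(features.index),
        oob_prediction=oob,
        cv_curve=curve,
    )


def healthy_line(
    chronological: pd.Series, microbial: pd.Series
) -> tuple[float, float, float]:
    """OLS of microbial age on chronological age: (intercept, slope, R2)."""
    x = np.asarray(chronological, dtype=float)
    y = np.asarray(microbial, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 healthy samples to fit the line")
    if np.ptp(x) == 0:
        raise ValidationError("chronological age is constant; line undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[0]), float(fit.params[1]), float(fit.rsquared)


def deviation_and_label(
    chronological_age: float, microbial_age: float, line: tuple[float, float]
) -> tuple[float, str]:
    """Deviation from the healthy line and the old/young label.

    old iff deviation > 0; a deviation of exactly 0 is young (the "old"
    category is defined strictly by a positive difference).
    """
    intercept, slope = line[0], line[1]
    fitted = intercept + slope * chronological_age
    dev = microbial_age - fitted
    return dev, ("old" if dev > 0 else "young")


def classify_and_apply(
    models: dict[str, MicrobialAgeModel],
    lines: dict[str, tuple[float, float]],
    features: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Microbial-age table for healthy (OOB) and diseased (applied) samples.

    Returns one row per sample: sex, chronological and microbial age, the
    deviation from the sex-specific healthy line, the old/young label and
    whether the prediction was out-of-bag or an application of the model.
    """
    rows = []
    for sex, model in models.items():
        line = lines[sex]
        sex_idx = metadata.index[metadata["sex"] == sex]
        sex_idx = sex_idx.intersection(features.index)
        train = [s for s in sex_idx if s in set(model.training_ids)]
        applied = [s for s in sex_idx if s not in set(model.training_ids)]
        preds = {}
        for s in train:
            preds[s] = (float(model.oob_prediction.loc[s]), "oob_training")
        if applied:
            pa = model.predict(features.loc[applied])
            for s in applied:
                preds[s] = (float(pa.loc[s]), "applied")
        for s, (ma, source) in preds.items():
            chron = float(metadata.loc[s, "age_years"])
            dev, label = deviation_and_label(chron, ma, line)
            rows.append(
                {
                    "sample_id": s,
                    "sex": sex,
                    "chronological_age": chron,
                    "microbial_age": ma,
                    "deviation": dev,
                    "label": label,
                    "source": source,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def group_contrast(
    ma: pd.DataFrame,
    metadata: pd.DataFrame,
    diseases,
    model_spec: int = 2,
) -> pd.DataFrame:
    """Microbial-age difference for each disease vs the healthy reference.

    Model 1 adjusts for chronological age; Model 2 additionally for BMI,
    energy intake, education, exercise, smoking and drinking; Model 3 adds
    medication indicators and drops analgesic/hormone users.
    """
    if model_spec not in (1, 2, 3):
        raise ValidationError("model_spec must be 1, 2 or 3")
    covs = MODEL1_COVARIATES if model_spec == 1 else MODEL2_COVARIATES
    meta = metadata.loc[ma.index].copy()
    if model_spec == 3:
        for c in MEDICATION_COLUMNS + EXCLUDE_USER_COLUMNS:
            if c not in meta.columns:
                raise ValidationError(f"Model 3 requires metadata column {c!r}")
        keep = ~(meta[list(EXCLUDE_USER_COLUMNS)].any(axis=1))
        meta = meta[keep]
    from .io import DISEASE_COLUMNS

    all_flags = [c for c in DISEASE_COLUMNS if c in meta.columns] or list(diseases)
    healthy = ~meta[all_flags].any(axis=1)
    rows = []
    for disease in diseases:
        flag = meta[disease].astype(bool)
        if not flag.any():
            warnings.warn(f"no cases for {disease!r}; skipped", stacklevel=2)
            continue
        use = healthy | flag
        sub = meta[use]
        X = pd.DataFrame({"disease": sub[disease].astype(float)}, index=sub.index)
        for c in covs:
            X[c] = sub[c].astype(float)
        if model_spec == 3:
            for c in MEDICATION_COLUMNS:
                X[c] = sub[c].astype(float)
        y = ma.loc[sub.index, "microbial_age"].to_numpy(dtype=float)
        Xd = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
            warnings.warn(f"rank-deficient design for {disease!r}; skipped", stacklevel=2)
            continue
        fit = sm.OLS(y, Xd).fit()
        ci = fit.conf_int().loc["disease"]
        rows.append(
            {
                "disease": disease,
                "difference": float(fit.params["disease"]),
                "se": float(fit.bse["disease"]),
                "ci_low": float(ci[0]),
                "ci_high": float(ci[1]),
                "p": float(fit.pvalues["disease"]),
                "n_cases": int(flag.sum()),
                "n": int(fit.nobs),
                "model": model_spec,
            }
        )
    return pd.DataFrame(rows)
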