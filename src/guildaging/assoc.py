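"""CLR transform, per-feature age models with sex interaction, BH-FDR, and
guild-level aggregation of predicted pathway contributions.

The abundance models are ordinary least squares on centered log-ratio (CLR)
values: zeros are replaced by a pseudo-count of 0.5 (half the minimum
nonzero count) before taking logs, and each sample is centered by its mean
log abundance, making the transform invariant to sequencing depth.  Each
feature is regressed on age plus covariates (BMI and total energy intake by
default), optionally per sex, and p-values are corrected across features by
Benjamini-Hochberg step-up — separately for the main age effects and for
the age x sex interaction family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .guilds import GuildPartition
from .io import ValidationError

DEFAULT_COVARIATES = ("bmi", "energy_kcal")


def clr_transform(counts: pd.DataFrame, pseudo: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform with zero replacement.

    Zeros are replaced by ``pseudo`` (0.5 on the count scale); then
    clr = log x - mean(log x) per sample, so rows sum to zero.
    """
    X = counts.to_numpy(dtype=float).copy()
    if np.any(X < 0):
        raise ValidationError("negative abundances are not allowed")
    if np.any(X.sum(axis=1) <= 0):
        raise ValidationError("all-zero sample")
    X[X == 0] = pseudo
    L = np.log(X)
    L -= L.mean(axis=1, keepdims=True)
    return pd.DataFrame(L, index=counts.index, columns=counts.columns)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fit_one(y: np.ndarray, X: pd.DataFrame):
    """OLS with a rank check; returns the fit or None if rank-deficient."""
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        return None
    return sm.OLS(y, Xd).fit()


def fit_feature_age_models(
    clr: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    stratify_by_sex: bool = True,
    with_interaction: bool = False,
) -> pd.DataFrame:
    """Per-feature linear models of CLR abundance on age.

    Returns one row per (feature, stratum) with the age coefficient, Wald
    95% CI, p and BH q.  With ``with_interaction`` a combined-sex fit with
    age, sex and age x sex is added and the interaction p-values corrected
    as their own family (stratum label ``interaction``).
    """
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise ValidationError(f"covariates not in metadata: {missing}")
    meta = metadata.loc[clr.index]
    strata: list[tuple[str, pd.Index]] = []
    if stratify_by_sex:
        for sex in ("male", "female"):
            idx = meta.index[meta["sex"] == sex]
            if len(idx):
                strata.append((sex, idx))
    else:
        strata.append(("all", meta.index))

    rows = []
    for label, idx in strata:
        sub = meta.loc[idx]
        X = pd.DataFrame({"age_years": sub["age_years"].astype(float)}, index=idx)
        for c in covariates:
            v = sub[c]
            X[c] = v.astype(float) if v.dtype != object else pd.factorize(v)[0]
        for feat in clr.columns:
            fit = _fit_one(clr.loc[idx, feat].to_numpy(), X)
            if fit is None:
                warnings.warn(
                    f"feature {feat!r} skipped in stratum {label!r}: "
                    "rank-deficient design",
                    stacklevel=2,
                )
                continue
            ci = fit.conf_int().loc["age_years"]
            rows.append(
                {
                    "feature": feat,
                    "stratum": label,
                    "beta": fit.params["age_years"],
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p": fit.pvalues["age_years"],
                    "n": int(fit.nobs),
                }
            )

    if with_interaction:
        sex_num = (meta["sex"] == "female").astype(float)
        X = pd.DataFrame(
            {
                "age_years": meta["age_years"].astype(float),
                "sex_female": sex_num,
                "age_x_sex": meta["age_years"].astype(float) * sex_num,
            },
            index=meta.index,
        )
        for c in covariates:
            v = meta[c]
            X[c] = v.astype(float) if v.dtype != object else pd.factorize(v)[0]
        for feat in clr.columns:
            fit = _fit_one(clr[feat].to_numpy(), X)
            if fit is None:
                warnings.warn(
                    f"feature {feat!r} skipped in interaction model: "
                    "rank-deficient design",
                    stacklevel=2,
                )
                continue
            ci = fit.conf_int().loc["age_x_sex"]
            rows.append(
                {
                    "feature": feat,
                    "stratum": "interaction",
                    "beta": fit.params["age_x_sex"],
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                    "p": fit.pvalues["age_x_sex"],
                    "n": int(fit.nobs),
                }
            )

    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    for label in out["stratum"].unique():
        mask = out["stratum"] == label
        out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out.reset_index(drop=True)


def aggregate_function_contributions(
    contributions: pd.DataFrame, partition: GuildPartition
) -> pd.DataFrame:
    """Mean log10 contribution (%) of each guild to each pathway.

    ``contributions`` is long-form with columns sample_id, otu_id, pathway,
    contribution_pct.  Member-OTU contributions are summed to guild level
    per sample and pathway, zeros replaced by a 0.001% pseudo-count, log10
    transformed, and averaged across samples.
    """
    required = {"sample_id", "otu_id", "pathway", "contribution_pct"}
    if not required <= set(contributions.columns):
        raise ValidationError(
            f"contribution table must have columns {sorted(required)}"
        )
    if contributions.empty:
        return pd.DataFrame()
    missing = set(contributions["otu_id"]) - set(partition.assignment)
    if missing:
        raise ValidationError(
            f"partition does not cover contributing OTU {sorted(missing)[0]!r}"
        )
    df = contributions.copy()
    df["guild_id"] = df["otu_id"].map(partition.assignment)
    per_sample = (
        df.groupby(["sample_id", "pathway", "guild_id"])["contribution_pct"]
        .sum()
        .unstack("guild_id", fill_value=0.0)
    )
    # complete the grid: guilds absent from a (sample, pathway) contribute 0
    all_guilds = sorted(set(partition.assignment.values()))
    per_sample = per_sample.reindex(columns=all_guilds, fill_value=0.0)
    samples = df["sample_id"].unique()
    pathways = df["pathway"].unique()
    grid = pd.MultiIndex.from_product([samples, pathways], names=["sample_id", "pathway"])
    per_sample = per_sample.reindex(grid, fill_value=0.0)
    logged = np.log10(per_sample.where(per_sample > 0, 0.001))
    out = logged.groupby(level="pathway").mean().T
    out.index.name = "guild_id"
    return out
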