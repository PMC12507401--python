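"""Rarefaction, alpha diversity, Bray-Curtis uniqueness, PCoA and PERMANOVA.

Conventions: Shannon entropy in natural log; Pielou evenness H / ln S with
J = 1 for a single-taxon sample; Chao1 in its bias-corrected form
S + F1 (F1 - 1) / (2 (F2 + 1)), which stays defined when no doubletons are
observed.  Uniqueness is a sample's minimum Bray-Curtis dissimilarity to any
other sample in the analysis set — larger means a more distinct microbiome.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import OtuTable, ValidationError


def rarefy(counts: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples below depth are an error (listed), never silently dropped.
    Accepts any samples x features count table (OTU- or guild-level).
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    X = counts.to_numpy()
    totals = X.sum(axis=1)
    under = counts.index[totals < depth]
    if len(under):
        raise ValidationError(
            f"samples below rarefaction depth {depth}: {list(under)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for s in range(X.shape[0]):
        if totals[s] == depth:
            out[s] = X[s]
        else:
            out[s] = rng.multivariate_hypergeometric(X[s].astype(np.int64), depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Chao1 (bias-corrected), Shannon (nats) and Pielou evenness."""
    X = counts.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = counts.index[totals <= 0][0]
        raise ValidationError(f"all-zero sample {bad!r}")
    rows = []
    for x, total in zip(X, totals):
        nz = x[x > 0]
        s = len(nz)
        f1 = int((nz == 1).sum())
        f2 = int((nz == 2).sum())
        chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = nz / total
        shannon = float(-(p * np.log(p)).sum())
        pielou = 1.0 if s == 1 else shannon / math.log(s)
        rows.append((chao1, shannon, pielou, s))
    return pd.DataFrame(
        rows, index=counts.index, columns=["chao1", "shannon", "pielou", "richness"]
    )


def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix on count rows."""
    totals = counts.to_numpy().sum(axis=1)
    if np.any(totals <= 0):
        raise ValidationError("Bray-Curtis undefined for an all-zero sample")
    D = squareform(pdist(counts.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(D, index=counts.index, columns=counts.index)


def uniqueness(D: pd.DataFrame) -> pd.Series:
    """Minimum off-diagonal dissimilarity per sample."""
    if D.shape[0] < 2:
        raise ValidationError("uniqueness needs at least 2 samples")
    A = D.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, np.inf)
    return pd.Series(A.min(axis=1), index=D.index, name="uniqueness")


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    exhaustive: bool = False


def _group_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float, int]:
    """Total and within-group sums of squared dissimilarities, and k."""
    n = D2.shape[0]
    sst = D2.sum() / (2.0 * n)
    ssw = 0.0
    codes, counts = np.unique(labels, return_counts=True)
    for g, ng in zip(codes, counts):
        idx = labels == g
        ssw += D2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return sst, ssw, len(codes)


def permanova(
    D: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA (Anderson's pseudo-F) with permutation p-value.

    ``exhaustive=True`` enumerates every distinct label assignment instead of
    sampling; p is then the exact fraction of assignments (the observed one
    included) whose pseudo-F is at least the observed.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(pd.factorize(np.asarray(groups))[0])
    n = D.shape[0]
    if len(labels) != n:
        raise ValidationError("groups not aligned with distance matrix")
    if len(np.unique(labels)) < 2:
        raise ValidationError("grouping is constant; PERMANOVA undefined")
    D2 = D**2

    def f_stat(lab: np.ndarray) -> float:
        sst, ssw, k = _group_ss(D2, lab)
        ssa = sst - ssw
        return (ssa / (k - 1)) / (ssw / (n - k))

    sst, ssw, k = _group_ss(D2, labels)
    ssa = sst - ssw
    f_obs = (ssa / (k - 1)) / (ssw / (n - k))
    r2 = ssa / sst

    if exhaustive:
        f_all = [
            f_stat(np.asarray(perm))
            for perm in _distinct_assignments(labels)
        ]
        p = sum(f >= f_obs - 1e-12 for f in f_all) / len(f_all)
        return PermanovaResult(f_obs, r2, p, len(f_all), exhaustive=True)

    rng = np.random.default_rng(seed)
    if k == 2:
        # vectorized two-group permutations via quadratic forms
        n1 = int((labels == 0).sum())
        P = np.zeros((n_permutations, n), dtype=float)
        for r in range(n_permutations):
            P[r, rng.permutation(n)[:n1]] = 1.0
        total = D2.sum()
        row = D2.sum(axis=1)
        q1 = ((P @ D2) * P).sum(axis=1)  # sum of D2 within group 1 (x2)
        q2 = total - 2.0 * (P @ row) + q1
        ssw_perm = q1 / (2.0 * n1) + q2 / (2.0 * (n - n1))
        f_perm = ((sst - ssw_perm) / (k - 1)) / (ssw_perm / (n - k))
        exceed = int((f_perm >= f_obs - 1e-12).sum())
    else:
        exceed = 0
        for _ in range(n_permutations):
            if f_stat(labels[rng.permutation(n)]) >= f_obs - 1e-12:
                exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return PermanovaResult(f_obs, r2, p, n_permutations)


def _distinct_assignments(labels: np.ndarray):
    """All distinct multiset permutations of a label vector (guarded size)."""
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    if total > 200_000:
        raise ValidationError(
            f"{total} distinct assignments is too many to enumerate"
        )
    if len(uniq) == 2:
        n1 = int(counts[0])
        base = np.full(n, uniq[1])
        for idx in itertools.combinations(range(n), n1):
            lab = base.copy()
            lab[list(idx)] = uniq[0]
            yield lab
    else:
        seen = set()
        for perm in itertools.permutations(labels):
            if perm not in seen:
                seen.add(perm)
                yield np.asarray(perm)


def permanova_terms(
    D: pd.DataFrame | np.ndarray,
    covariates: pd.DataFrame,
    terms: list[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sequential (Type I) multi-term PERMANOVA on a Gower-centered matrix.

    Each term's sum of squares is the gain in explained inertia when added
    after the preceding terms; p-values permute the samples of the centered
    inner-product matrix.  Used for univariate covariate screens one term at
    a time, or a short sequential model.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    G = _gower_center(D)
    rng = np.random.default_rng(seed)

    def design(term_list: list[str]) -> np.ndarray:
        cols = [np.ones(n)]
        for t in term_list:
            v = covariates[t]
            if v.dtype == object or v.dtype == bool or str(v.dtype) == "category":
                dummies = pd.get_dummies(v, drop_first=True).to_numpy(dtype=float)
                cols.append(dummies)
            else:
                cols.append(v.to_numpy(dtype=float)[:, None])
        return np.column_stack(cols)

    def hat(X: np.ndarray) -> np.ndarray:
        return X @ np.linalg.pinv(X.T @ X) @ X.T

    full = design(terms)
    H_full = hat(full)
    trG = np.trace(G)
    ss_res = trG - np.trace(H_full @ G)
    df_res = n - np.linalg.matrix_rank(full)
    rows = []
    for i, term in enumerate(terms):
        H0 = hat(design(terms[:i]))
        H1 = hat(design(terms[: i + 1]))
        df_t = np.linalg.matrix_rank(design(terms[: i + 1])) - np.linalg.matrix_rank(
            design(terms[:i])
        )
        ss_t = np.trace((H1 - H0) @ G)
        f_obs = (ss_t / df_t) / (ss_res / df_res)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            ss_tp = np.trace((H1 - H0) @ Gp)
            ss_rp = trG - np.trace(H_full @ Gp)
            if (ss_tp / df_t) / (ss_rp / df_res) >= f_obs - 1e-12:
                exceed += 1
        rows.append(
            {
                "term": term,
                "pseudo_F": f_obs,
                "R2": ss_t / trG,
                "p": (1.0 + exceed) / (n_permutations + 1.0),
            }
        )
    return pd.DataFrame(rows)


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    age_slopes: np.ndarray  # OLS slope of each retained axis score on age
    age_arrow: np.ndarray  # slopes rescaled to the coordinate range
    negative_eigenvalue_mass: float


def pcoa_with_age_arrow(
    D: pd.DataFrame,
    ages,
    top_axes: int = 2,
    arrow_fraction: float = 0.8,
) -> PcoaResult:
    """Classical PCoA plus the age-regression arrow of the retained axes.

    Negative eigenvalues (non-Euclidean dissimilarities) are dropped and
    their mass recorded.  The arrow is the vector of per-axis OLS slopes of
    axis score on age, rescaled so its length is ``arrow_fraction`` of the
    maximum coordinate radius.
    """
    idx = D.index if isinstance(D, pd.DataFrame) else pd.RangeIndex(len(D))
    A = np.asarray(D, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValidationError("dissimilarity matrix must be symmetric")
    G = _gower_center(A)
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    neg_mass = float(-vals[vals < 0].sum())
    vals_pos, vecs_pos = vals[pos], vecs[:, pos]
    k = min(top_axes, len(vals_pos))
    coords = vecs_pos[:, :k] * np.sqrt(vals_pos[:k])
    var_exp = vals_pos[:k] / vals_pos.sum()

    ages = np.asarray(ages, dtype=float)
    xc = ages - ages.mean()
    denom = (xc**2).sum()
    slopes = coords.T @ xc / denom
    radius = np.abs(coords).max() if coords.size else 0.0
    norm = np.linalg.norm(slopes)
    arrow = (
        slopes * (arrow_fraction * radius / norm) if norm > 0 else np.zeros_like(slopes)
    )
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=idx, columns=[f"PCoA{i+1}" for i in range(k)]
        ),
        eigenvalues=vals_pos,
        variance_explained=var_exp,
        age_slopes=slopes,
        age_arrow=arrow,
        negative_eigenvalue_mass=neg_mass,
    )


def diversity_profile(
    counts: pd.DataFrame, depth: int | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Rarefy (optionally), then alpha diversity plus Bray-Curtis uniqueness."""
    if depth is not None:
        counts = rarefy(counts, depth, seed=seed)
    prof = alpha_diversity(counts)
    prof["uniqueness"] = uniqueness(bray_curtis(counts))
    return prof


def two_group_permanova_fast(
    D2: np.ndarray, mask: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Pseudo-F and permutation p for a two-group split given squared distances.

    Shared fast path for the guild-tree cutter: ``mask`` flags group-1
    members.  Returns (F, p) with the add-one permutation estimator.
    """
    n = D2.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    total = D2.sum()
    row = D2.sum(axis=1)
    sst = total / (2.0 * n)
    w = mask.astype(float)
    q1 = w @ D2 @ w
    q2 = total - 2.0 * (w @ row) + q1
    ssw = q1 / (2.0 * n1) + q2 / (2.0 * n2)
    f_obs = (sst - ssw) / (ssw / (n - 2))
    P = np.zeros((n_permutations, n), dtype=float)
    for r in range(n_permutations):
        P[r, rng.permutation(n)[:n1]] = 1.0
    q1p = ((P @ D2) * P).sum(axis=1)
    q2p = total - 2.0 * (P @ row) + q1p
    sswp = q1p / (2.0 * n1) + q2p / (2.0 * n2)
    fp = (sst - sswp) / (sswp / (n - 2))
    p = (1.0 + int((fp >= f_obs - 1e-12).sum())) / (n_permutations + 1.0)
    return float(f_obs), float(p)
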