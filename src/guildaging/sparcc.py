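"""SparCC: compositionally robust correlations between OTUs.

Relative abundances from sequencing are compositional, so naive Pearson
correlations of fractions are distorted by the closure.  SparCC instead works
from log-ratio variances, which are invariant to per-sample scaling:

    t_ij = Var_s[ log(x_is / x_js) ] = w_i^2 + w_j^2 - 2 rho_ij w_i w_j

where ``w_i^2`` is the variance of the (unobserved) basis log-abundance of
component i.  Under a sparsity assumption (most true correlations are near
zero) the cross terms vanish on average and the basis variances satisfy the
linear system

    sum_{j != i} t_ij  ~=  (p - 1) w_i^2 + sum_{j != i} w_j^2,

solved here by least squares.  Correlations follow by inversion of the t_ij
identity, and strongly correlated pairs — which violate sparsity — are
iteratively excluded from the system and the solve repeated.

Significance is assessed by permutation: each OTU's counts are shuffled
across samples independently, the full estimator re-run, and a two-sided
add-one p-value computed per pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import OtuTable, ValidationError

DEFAULT_PSEUDO = 0.5  # half of the minimum nonzero count, as for the CLR
_VARIANCE_FLOOR = 1e-10


@dataclass
class SparccResult:
    """Symmetric correlation estimate with the quantities used to derive it."""

    otu_ids: list[str]
    rho: np.ndarray
    basis_variance: np.ndarray
    n_iterations_used: int
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    pvalue: np.ndarray | None = None

    def rho_of(self, a: str, b: str) -> float:
        i, j = self.otu_ids.index(a), self.otu_ids.index(b)
        return float(self.rho[i, j])


def log_ratio_variance(t: OtuTable, pseudo: float = DEFAULT_PSEUDO) -> np.ndarray:
    """Matrix of sample variances of log((x_i + pseudo) / (x_j + pseudo)).

    Uses the n-1 (sample) variance.  The diagonal is exactly zero.
    """
    if pseudo <= 0:
        raise ValidationError("pseudo-count must be > 0")
    if t.n_samples < 3:
        raise ValidationError("log-ratio variance needs at least 3 samples")
    logs = np.log(t.counts.to_numpy(dtype=float) + pseudo)
    cov = np.cov(logs, rowvar=False, ddof=1)
    v = np.diag(cov)
    T = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(T, 0.0)
    # numerical cancellation can leave tiny negatives
    return np.maximum(T, 0.0)


def _solve_basis_variances(T: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Least-squares solve of the sparsity-approximated variance system.

    ``allowed[i, j]`` is False for pairs excluded from the system.  Row i of
    the design is: |S_i| on the diagonal, 1 for each allowed partner.
    """
    p = T.shape[0]
    A = allowed.astype(float)
    np.fill_diagonal(A, allowed.sum(axis=1))
    b = (T * allowed).sum(axis=1)
    if np.linalg.matrix_rank(A) < p:
        raise ValidationError(
            "basis-variance system is singular after pair exclusions; "
            "reduce max_exclude_rounds or raise exclude_threshold"
        )
    omega2, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(omega2 <= 0):
        warnings.warn(
            "negative basis variances floored at a small positive epsilon",
            stacklevel=2,
        )
        omega2 = np.maximum(omega2, _VARIANCE_FLOOR)
    return omega2


def _rho_from_variances(T: np.ndarray, omega2: np.ndarray) -> np.ndarray:
    w = np.sqrt(omega2)
    rho = (omega2[:, None] + omega2[None, :] - T) / (2.0 * np.outer(w, w))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


def estimate_basis_correlations(
    T: np.ndarray,
    otu_ids: list[str] | None = None,
    max_exclude_rounds: int = 10,
    exclude_threshold: float = 0.8,
) -> SparccResult:
    """Estimate basis correlations from a log-ratio variance matrix.

    One strongly correlated pair (|rho| above ``exclude_threshold``) is
    excluded from the variance system per round, up to ``max_exclude_rounds``
    rounds, as in the original SparCC iteration.
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if T.shape[0] != T.shape[1] or not np.allclose(T, T.T, atol=1e-8):
        raise ValidationError("T must be a symmetric square matrix")
    if p < 4:
        raise ValidationError("need at least 4 components to solve the system")
    if np.any(np.abs(np.diag(T)) > 1e-12):
        raise ValidationError("T must have a zero diagonal")
    ids = list(otu_ids) if otu_ids is not None else [f"OTU{i}" for i in range(p)]

    allowed = ~np.eye(p, dtype=bool)
    excluded: list[tuple[str, str]] = []
    rounds = 0
    omega2 = _solve_basis_variances(T, allowed)
    rho = _rho_from_variances(T, omega2)
    for rounds in range(1, max_exclude_rounds + 1):
        cand = np.abs(rho) * allowed
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclude_threshold:
            rounds -= 1
            break
        allowed[i, j] = allowed[j, i] = False
        excluded.append((ids[min(i, j)], ids[max(i, j)]))
        omega2 = _solve_basis_variances(T, allowed)
        rho = _rho_from_variances(T, omega2)
    return SparccResult(
        otu_ids=ids,
        rho=rho,
        basis_variance=omega2,
        n_iterations_used=rounds,
        excluded_pairs=excluded,
    )


def estimate_correlations(
    t: OtuTable,
    pseudo: float = DEFAULT_PSEUDO,
    max_exclude_rounds: int = 10,
    exclude_threshold: float = 0.8,
) -> SparccResult:
    """Convenience: log-ratio variances then the basis-correlation solve."""
    T = log_ratio_variance(t, pseudo=pseudo)
    return estimate_basis_correlations(
        T,
        otu_ids=t.otu_ids,
        max_exclude_rounds=max_exclude_rounds,
        exclude_threshold=exclude_threshold,
    )


def sparcc_pvalues(
    t: OtuTable,
    observed: SparccResult,
    n_permutations: int = 999,
    seed: int | None = None,
    pseudo: float = DEFAULT_PSEUDO,
    max_exclude_rounds: int = 10,
    exclude_threshold: float = 0.8,
) -> np.ndarray:
    """Two-sided permutation p-values for every OTU pair.

    Each permutation shuffles every OTU's counts across samples
    independently (destroying all cross-OTU alignment while preserving
    marginals) and re-runs the full estimator.  p = (1 + #{|rho*| >= |rho|})
    / (n_permutations + 1); with R permutations the smallest attainable p is
    1 / (R + 1).
    """
    if n_permutations < 19:
        raise ValidationError("need at least 19 permutations")
    rng = np.random.default_rng(seed)
    X = t.counts.to_numpy(dtype=float)
    n, p = X.shape
    obs = np.abs(observed.rho)
    exceed = np.zeros((p, p), dtype=np.int64)
    import pandas as pd

    for _ in range(n_permutations):
        perm = np.empty_like(X)
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        pt = OtuTable(
            pd.DataFrame(perm.astype(np.int64), index=t.sample_ids, columns=t.otu_ids)
        )
        r = estimate_correlations(
            pt,
            pseudo=pseudo,
            max_exclude_rounds=max_exclude_rounds,
            exclude_threshold=exclude_threshold,
        )
        exceed += np.abs(r.rho) >= obs
    pval = (1.0 + exceed) / (n_permutations + 1.0)
    np.fill_diagonal(pval, 0.0)
    pval = np.minimum(pval, pval.T)
    observed.pvalue = pval
    return pval


def brute_force_basis_solve(T: np.ndarray) -> np.ndarray:
    """Independent dense solve of the variance system, for cross-checking.

    Writes out one least-squares row per component explicitly from the
    pairwise identities, with no shared code with the estimator.
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    rows, rhs = [], []
    for i in range(p):
        row = np.ones(p)
        row[i] = p - 1
        rows.append(row)
        rhs.append(sum(T[i, j] for j in range(p) if j != i))
    omega2, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    omega2 = np.maximum(omega2, _VARIANCE_FLOOR)
    rho = np.empty((p, p))
    for i, j in itertools.product(range(p), range(p)):
        if i == j:
            rho[i, j] = 1.0
        else:
            rho[i, j] = (omega2[i] + omega2[j] - T[i, j]) / (
                2.0 * np.sqrt(omega2[i] * omega2[j])
            )
    return np.clip(rho, -1.0, 1.0)
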