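"""Pairwise distance regression of community-structure maps on covariates.

Subject SI maps are compared pairwise with the weighted-Jaccard (Ruzicka)
similarity; 1 - similarity gives the brain distance. Covariates enter as
absolute pairwise differences (binary covariates as mismatch indicators).
The upper-triangle pairs are regressed on the covariate distances plus an
intercept and subject fixed-effect indicators (each pair loads on both of its
subjects; one indicator dropped for identifiability). Parametric p-values use
the standard-normal reference; a subject-level permutation p-value is
available for any single term. Families of p-values are adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .scaled_inclusivity import SIMap

__all__ = [
    "PairDistanceMatrix",
    "TermResult",
    "DistanceModelResult",
    "ruzicka_similarity",
    "brain_distance_matrix",
    "covariate_distance_matrix",
    "fit_distance_regression",
    "adapted_fdr",
    "results_to_table",
]


@dataclass
class PairDistanceMatrix:
    subject_ids: tuple[str, ...]
    values: np.ndarray
    kind: str  # brain_jaccard | abs_numeric | binary_mismatch

    def __post_init__(self) -> None:
        self.subject_ids = tuple(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.subject_ids)
        if self.values.shape != (m, m):
            raise ValueError("distance matrix shape does not match subject list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subject_id\t" + "\t".join(self.subject_ids) + "\n")
            for sid, row in zip(self.subject_ids, self.values):
                fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class TermResult:
    name: str
    estimate: float
    se: float
    t_score: float
    p_value: float
    p_permutation: Optional[float] = None


@dataclass
class DistanceModelResult:
    network: str
    condition: str
    terms: list[TermResult]
    n_subjects: int
    n_pairs: int
    p_fdr: Optional[float] = None  # family-adjusted p for the term of interest

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def ruzicka_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted-Jaccard similarity sum(min)/sum(max) of nonnegative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be nonnegative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero; similarity undefined")
    return float(np.minimum(x, y).sum() / denom)


def brain_distance_matrix(maps: Sequence[SIMap]) -> PairDistanceMatrix:
    """Pairwise 1 - Ruzicka similarity between subject SI maps."""
    n = len(maps)
    stack = np.stack([np.asarray(m.values, dtype=float) for m in maps])
    mins = np.minimum(stack[:, None, :], stack[None, :, :]).sum(axis=2)
    maxs = np.maximum(stack[:, None, :], stack[None, :, :]).sum(axis=2)
    if np.any(maxs == 0):
        raise ValueError("a subject pair has all-zero SI maps; distance undefined")
    D = 1.0 - mins / maxs
    np.fill_diagonal(D, 0.0)
    return PairDistanceMatrix(tuple(m.subject_id for m in maps), D, "brain_jaccard")


def covariate_distance_matrix(
    values: Sequence[float],
    kind: str,
    subject_ids: Optional[Sequence[str]] = None,
) -> PairDistanceMatrix:
    """Absolute pairwise differences (numeric) or mismatch indicators (binary)."""
    v = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(v)):
        raise ValueError("covariate contains missing values")
    if subject_ids is None:
        subject_ids = tuple(str(i) for i in range(v.size))
    if kind == "abs_numeric":
        D = np.abs(v[:, None] - v[None, :])
    elif kind == "binary_mismatch":
        if not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("binary covariate must be coded 0/1")
        D = (v[:, None] != v[None, :]).astype(float)
    else:
        raise ValueError(f"unknown distance kind {kind!r}")
    return PairDistanceMatrix(tuple(subject_ids), D, kind)


def _design(y: PairDistanceMatrix, xs: Sequence[PairDistanceMatrix],
            term_names: Sequence[str]):
    m = y.n_subjects
    for x in xs:
        if x.subject_ids != y.subject_ids:
            raise ValueError("distance matrices do not share subject order")
    if len(xs) != len(term_names):
        raise ValueError("need one name per predictor matrix")
    iu, ju = np.triu_indices(m, k=1)
    n_pairs = iu.size
    dummies = np.zeros((n_pairs, m))
    rows = np.arange(n_pairs)
    dummies[rows, iu] = 1.0
    dummies[rows, ju] = 1.0
    X = np.column_stack(
        [np.ones(n_pairs)]
        + [x.values[iu, ju] for x in xs]
        + [dummies[:, :-1]]  # last subject dummy dropped for identifiability
    )
    names = (
        ["intercept"]
        + list(term_names)
        + [f"subject[{sid}]" for sid in y.subject_ids[:-1]]
    )
    return X, names, y.values[iu, ju], (iu, ju)


def _ols(X: np.ndarray, yy: np.ndarray):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    dof = n - p
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, dof


def fit_distance_regression(
    y: PairDistanceMatrix,
    xs: Sequence[PairDistanceMatrix],
    term_names: Sequence[str],
    *,
    network: str = "",
    condition: str = "",
    permute_term: Optional[str] = None,
    n_permutations: int = 0,
    seed: Optional[int] = None,
) -> DistanceModelResult:
    """OLS on unrolled upper-triangle pairs with subject fixed effects.

    Two-sided p-values come from the standard-normal reference (the pair count
    is large). If ``permute_term`` names one of ``term_names`` and
    ``n_permutations`` > 0, a permutation p-value for that term is computed by
    jointly permuting that covariate's subject values (equivalently, permuting
    rows and columns of its distance matrix), refitting, and comparing |T|.
    """
    m = y.n_subjects
    if m < 10:
        raise ValueError("distance regression requires at least 10 subjects")
    X, names, yy, (iu, ju) = _design(y, xs, term_names)
    beta, se, dof = _ols(X, yy)
    t_scores = beta / se
    p_values = 2.0 * norm.sf(np.abs(t_scores))

    terms = [
        TermResult(nm, float(beta[k]), float(se[k]), float(t_scores[k]),
                   float(p_values[k]))
        for k, nm in enumerate(names)
        if nm in term_names
    ]
    result = DistanceModelResult(network, condition, terms, m, yy.size)

    if permute_term is not None and n_permutations > 0:
        j = names.index(permute_term)
        xj_matrix = xs[list(term_names).index(permute_term)].values
        Z = np.delete(X, j, axis=1)
        Q, _ = np.linalg.qr(Z)
        y_t = yy - Q @ (Q.T @ yy)
        n, p = X.shape

        def _fwl_t(xcol: np.ndarray) -> float:
            x_t = xcol - Q @ (Q.T @ xcol)
            sxx = x_t @ x_t
            if sxx <= 0:
                return 0.0
            b = (x_t @ y_t) / sxx
            rss = y_t @ y_t - b * b * sxx
            return float(b / np.sqrt(rss / dof / sxx))

        t_obs = _fwl_t(X[:, j])
        rng = np.random.default_rng(seed)
        # batch-residualize all permuted columns in one pass
        cols = np.empty((yy.size, n_permutations))
        for b in range(n_permutations):
            perm = rng.permutation(m)
            cols[:, b] = xj_matrix[np.ix_(perm, perm)][iu, ju]
        cols_t = cols - Q @ (Q.T @ cols)
        sxx = np.einsum("ij,ij->j", cols_t, cols_t)
        sxy = y_t @ cols_t
        with np.errstate(divide="ignore", invalid="ignore"):
            bs = np.where(sxx > 0, sxy / sxx, 0.0)
            rss = y_t @ y_t - bs * bs * sxx
            t_perm = np.where(sxx > 0, bs / np.sqrt(rss / dof / sxx), 0.0)
        exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
        p_perm = (1 + exceed) / (n_permutations + 1)
        result.term(permute_term).p_permutation = float(p_perm)
    return result


def adapted_fdr(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted p-values, mapped back to the input order.

    ``method='bh'`` is the Benjamini-Hochberg step-up adjustment
    q_(k) = min_{j >= k} min(1, m * p_(j) / j); ``method='two-stage'`` is the
    Benjamini-Krieger-Yekutieli two-stage adaptive variant.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "two-stage":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_tsbh")[1]
    if method != "bh":
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q_sorted
    return out


def results_to_table(
    results: Sequence[DistanceModelResult],
    fdr_term: str = "cs",
    method: str = "bh",
):
    """Flat results table; the FDR column adjusts ``fdr_term`` p-values only,
    across the whole family of models (one value per model)."""
    import pandas as pd

    raw = [r.term(fdr_term).p_value for r in results]
    adjusted = adapted_fdr(raw, method=method)
    for r, q in zip(results, adjusted):
        r.p_fdr = float(q)
    rows = []
    for r in results:
        for t in r.terms:
            rows.append({
                "network": r.network,
                "condition": r.condition,
                "term": t.name,
                "estimate": t.estimate,
                "se": t.se,
                "t_score": t.t_score,
                "p_value": t.p_value,
                "p_permutation": t.p_permutation,
                "p_fdr": r.p_fdr if t.name == fdr_term else None,
            })
    return pd.DataFrame(rows)
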