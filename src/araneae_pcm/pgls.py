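"""Phylogenetic generalized least squares under Brownian covariance.

The regression model is ``y = X b + e`` with ``e ~ N(0, sigma2 * V)``
where V is the Brownian covariance implied by the tree.  Estimation
whitens both sides with the Cholesky factor of V and solves ordinary
least squares in the whitened space:

    b_hat = (X' V^-1 X)^-1 X' V^-1 y

With maximum likelihood (the default), ``sigma2 = RSS_V / n`` and the
log-likelihood is the multivariate normal at the profile optimum; AICc
counts the residual variance as one parameter.  Model selection fits all
non-empty predictor subsets and ranks them by AICc with Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist, f as f_dist

from araneae_pcm.treekit import PhyloTree, vcv_matrix

__all__ = [
    "DesignSpec", "PGLSFit", "fit_pgls", "model_selection", "anova_gls",
    "run_pgls_suite",
]

PREDICTORS = ["Strategy", "Specific", "Silk", "Type", "Instar"]

RESPONSES_ADULT = [
    "Fem_ALS_MAP", "Fem_ALS_PI", "Fem_PMS_mAP", "Fem_PMS_AC",
    "Fem_PMS_CY", "Fem_PLS_AC", "Fem_PLS_CY",
]
RESPONSES_SECOND = [
    "Sec_ALS_MAP", "Sec_ALS_PI", "Sec_PMS_mAP", "Sec_PMS_AC", "Sec_PLS_AC",
]
RESPONSES = RESPONSES_ADULT + RESPONSES_SECOND


@dataclass
class DesignSpec:
    response: str
    predictors: list[str] = field(default_factory=list)
    intercept: bool = True

    def __post_init__(self) -> None:
        if len(self.predictors) > 5:
            raise ValueError("at most five predictors")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("duplicate predictors")


@dataclass
class PGLSFit:
    spec: DesignSpec
    terms: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    sigma2: float
    loglik: float
    aicc: float
    n: int
    k: int
    method: str
    rank_warning: bool = False

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def tvalue(self, term: str) -> float:
        return float(self.t_values[self.terms.index(term)])

    def pvalue(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "t": self.t_values,
                "p": self.p_values,
            },
            index=self.terms,
        )


def _aligned_matrix(tree: PhyloTree, table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    tips = tree.tip_labels
    missing = sorted(set(tips) ^ set(table.index))
    if missing:
        raise ValueError(f"tip/table mismatch: {missing}")
    return vcv_matrix(tree).matrix, tips


def fit_pgls(
    tree: PhyloTree,
    table: pd.DataFrame,
    spec: DesignSpec,
    method: str = "ML",
) -> PGLSFit:
    """Fit one PGLS model; see module docstring for the conventions."""
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    V, tips = _aligned_matrix(tree, table)
    sub = table.loc[tips]
    for col in [spec.response, *spec.predictors]:
        if col not in sub.columns:
            raise ValueError(f"column {col!r} missing from trait table")
    y = sub[spec.response].to_numpy(dtype=float)
    cols: list[str] = []
    Xparts: list[np.ndarray] = []
    if spec.intercept:
        cols.append("(Intercept)")
        Xparts.append(np.ones(len(y)))
    for name in spec.predictors:
        cols.append(name)
        Xparts.append(sub[name].to_numpy(dtype=float))
    if not cols:
        raise ValueError("empty design: need an intercept or predictors")
    X = np.column_stack(Xparts)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few observations (n={n}) for {p} terms")

    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    # rank check on the whitened design
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        raise ValueError(
            f"rank-deficient design for response {spec.response!r}: "
            f"collinear terms among {cols}"
        )
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    rank_warning = rss < 1e-12

    if method == "ML":
        sigma2 = rss / n
    else:
        sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    df = n - p
    pvals = 2 * t_dist.sf(np.abs(tvals), df)

    sign, logdetV = np.linalg.slogdet(V)
    sigma2_ml = rss / n
    loglik = float(-0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetV + n))
    k = p + 1  # residual variance counts as a parameter
    if n - k - 1 > 0:
        aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    else:
        aicc = np.inf
    return PGLSFit(
        spec=spec, terms=cols, coefficients=beta, std_errors=se,
        t_values=np.asarray(tvals, dtype=float), p_values=np.asarray(pvals, dtype=float),
        sigma2=sigma2, loglik=loglik, aicc=float(aicc), n=n, k=k,
        method=method, rank_warning=rank_warning,
    )


def model_selection(
    tree: PhyloTree,
    table: pd.DataFrame,
    response: str,
    candidate_terms: Iterable[str] = tuple(PREDICTORS),
    max_terms: int = 5,
) -> pd.DataFrame:
    """AICc ranking of all non-empty predictor subsets up to ``max_terms``.

    Returns a frame sorted ascending by AICc with delta values and Akaike
    weights ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``.
    """
    candidates = list(candidate_terms)
    if not 1 <= max_terms <= 5:
        raise ValueError("max_terms must be in 1..5")
    rows = []
    for size in range(1, min(max_terms, len(candidates)) + 1):
        for terms in combinations(candidates, size):
            spec = DesignSpec(response=response, predictors=list(terms))
            try:
                fit = fit_pgls(tree, table, spec)
            except ValueError as exc:
                raise ValueError(f"model {'+'.join(terms)} failed: {exc}") from exc
            rows.append({"model": "+".join(terms), "terms": terms,
                         "aicc": fit.aicc, "loglik": fit.loglik, "k": fit.k})
    frame = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    frame["delta"] = frame["aicc"] - frame["aicc"].iloc[0]
    rel = np.exp(-0.5 * frame["delta"].to_numpy())
    frame["weight"] = rel / rel.sum()
    return frame


def anova_gls(fit: PGLSFit, tree: PhyloTree, table: pd.DataFrame) -> pd.DataFrame:
    """Sequential (type-I) F tests on the V-whitened model.

    Terms are added in the order they appear in the design; each row
    tests the reduction in residual sum of squares against the residual
    mean square of the full model.
    """
    preds = fit.spec.predictors
    if not preds:
        return pd.DataFrame(columns=["term", "df", "F", "p"])
    V, tips = _aligned_matrix(tree, table)
    sub = table.loc[tips]
    y = sub[fit.spec.response].to_numpy(dtype=float)
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)

    def rss_for(terms: list[str]) -> float:
        parts = [np.ones(len(yw))] if fit.spec.intercept else []
        for t_ in terms:
            parts.append(sub[t_].to_numpy(dtype=float))
        Xw = np.linalg.solve(L, np.column_stack(parts)) if parts else None
        if Xw is None:
            return float(yw @ yw)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        return float(r @ r)

    n = len(yw)
    p_full = len(preds) + (1 if fit.spec.intercept else 0)
    df_resid = n - p_full
    rss_full = rss_for(preds)
    ms_resid = rss_full / df_resid
    rows = []
    prev = rss_for([])
    for i, term in enumerate(preds):
        cur = rss_for(preds[: i + 1])
        F = max(0.0, (prev - cur) / 1.0 / ms_resid)
        rows.append({
            "term": term, "df": 1, "F": F,
            "p": float(f_dist.sf(F, 1, df_resid)),
        })
        prev = cur
    return pd.DataFrame(rows)


def run_pgls_suite(
    tree: PhyloTree,
    table: pd.DataFrame,
    responses: Optional[list[str]] = None,
    predictors: Optional[list[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All single-term PGLS fits (response x predictor grid).

    On the full study design this is 12 responses x 5 predictors = 60
    models; each row carries the slope, t, p and a significance flag at
    ``alpha``.
    """
    responses = list(responses) if responses is not None else list(RESPONSES)
    predictors = list(predictors) if predictors is not None else list(PREDICTORS)
    if table.empty:
        raise ValueError("empty trait table")
    missing = [c for c in responses + predictors if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns in trait table: {missing}")
    rows = []
    for resp in responses:
        for pred in predictors:
            fit = fit_pgls(tree, table, DesignSpec(response=resp, predictors=[pred]))
            rows.append({
                "response": resp, "predictor": pred,
                "coefficient": fit.coef(pred), "t": fit.tvalue(pred),
                "p": fit.pvalue(pred), "aicc": fit.aicc,
                "loglik": fit.loglik,
                "significant": fit.pvalue(pred) < alpha,
            })
    return pd.DataFrame(rows)
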