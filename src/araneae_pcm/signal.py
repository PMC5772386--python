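"""Phylogenetic signal statistics: Blomberg's K and Pagel's lambda.

Blomberg's K compares the observed partitioning of trait variance on the
tree with its Brownian-motion expectation::

    K = [ (y - a1)'(y - a1) / (y - a1)' V^{-1} (y - a1) ]
        / [ (tr(V) - n / (1' V^{-1} 1)) / (n - 1) ]

where ``a = (1' V^{-1} y) / (1' V^{-1} 1)`` is the phylogenetically
weighted mean.  K = 1 under Brownian motion; K < 1 means less signal than
Brownian expectation.  Its p-value comes from shuffling trait values
across tips.

Pagel's lambda multiplies the off-diagonal of V; the ML estimate is found
by profiling the multivariate-normal likelihood over the mean and rate
(closed form) and optimizing the remaining 1-D function of lambda.  The
p-value is a likelihood-ratio test against lambda = 0 (no signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from araneae_pcm.treekit import PhyloTree, vcv_matrix, lambda_transform

__all__ = ["SignalResult", "blomberg_k", "blomberg_k_test", "pagel_lambda_ml"]


@dataclass
class SignalResult:
    statistic_name: str
    estimate: float
    p_value: float
    n_permutations: Optional[int] = None
    loglik_at_estimate: Optional[float] = None
    loglik_at_null: Optional[float] = None


def _trait_vector(tree: PhyloTree, trait: Mapping[str, float]) -> np.ndarray:
    labels = tree.tip_labels
    missing = [t for t in labels if t not in trait]
    if missing:
        raise ValueError(f"trait missing for tips: {missing}")
    y = np.array([float(trait[t]) for t in labels])
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    if np.allclose(y, y[0]):
        raise ValueError("zero variance: trait is constant across tips")
    return y


def _k_statistic(y: np.ndarray, V: np.ndarray) -> float:
    n = len(y)
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    denom_w = one @ Vinv @ one
    a_hat = (one @ Vinv @ y) / denom_w
    r = y - a_hat
    mse0 = (r @ r)
    mse = r @ Vinv @ r
    expected = (np.trace(V) - n / denom_w) / (n - 1)
    return float((mse0 / mse) / expected)


def blomberg_k(tree: PhyloTree, trait: Mapping[str, float]) -> float:
    y = _trait_vector(tree, trait)
    V = vcv_matrix(tree).matrix
    return _k_statistic(y, V)


def blomberg_k_test(
    tree: PhyloTree,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Randomization test: shuffle trait values across tips; one-sided
    p = (1 + #{K_perm >= K_obs}) / (n_perm + 1), ties counted as >=."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    y = _trait_vector(tree, trait)
    V = vcv_matrix(tree).matrix
    k_obs = _k_statistic(y, V)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        k_perm = _k_statistic(rng.permutation(y), V)
        if k_perm >= k_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return SignalResult("K", k_obs, p, n_permutations=n_perm)


def _profile_loglik(y: np.ndarray, V: np.ndarray) -> float:
    """MVN log-likelihood profiled over the mean and overall rate sigma2."""
    n = len(y)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    a_hat = (one @ Vinv @ y) / (one @ Vinv @ one)
    r = y - a_hat
    sigma2 = (r @ Vinv @ r) / n
    if sigma2 <= 0:
        return -np.inf
    return float(-0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n))


def _lambda_max(V: np.ndarray, cap: float = 1.0) -> float:
    """Largest lambda keeping V(lambda) positive definite, capped.

    For ultrametric trees the cap of 1 is binding; for safety shrink from
    the cap until the Cholesky factorization succeeds.
    """
    lam = cap
    for _ in range(60):
        W = V * lam
        np.fill_diagonal(W, np.diag(V))
        try:
            np.linalg.cholesky(W)
            return lam
        except np.linalg.LinAlgError:
            lam *= 0.95
    raise ValueError("could not find a positive-definite lambda transform")


def pagel_lambda_ml(
    tree: PhyloTree,
    trait: Mapping[str, float],
    lambda_cap: float = 1.0,
) -> SignalResult:
    y = _trait_vector(tree, trait)
    V0 = vcv_matrix(tree)
    V = V0.matrix
    lam_max = _lambda_max(V, lambda_cap)

    def nll(lam: float) -> float:
        W = lambda_transform(V0, lam).matrix
        return -_profile_loglik(y, W)

    res = minimize_scalar(nll, bounds=(0.0, lam_max), method="bounded",
                          options={"xatol": 1e-8})
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    # the bounded optimizer keeps away from the exact bounds; snap to a
    # boundary when it is at least as good
    for bound in (0.0, lam_max):
        ll_bound = -nll(bound)
        if ll_bound >= ll_hat:
            lam_hat, ll_hat = bound, ll_bound
    ll_null = -nll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll_null))
    p = float(chi2.sf(lr, df=1))
    if lam_hat == 0.0:
        p = 1.0
    return SignalResult(
        "lambda", lam_hat, p,
        loglik_at_estimate=ll_hat, loglik_at_null=ll_null,
    )
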