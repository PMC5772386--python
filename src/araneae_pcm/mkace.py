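"""Constrained one-rate Mk models and ML ancestral character estimation.

A discrete character with ``k`` nominal states evolves along the tree as a
continuous-time Markov chain whose generator ``Q`` has ``Q[i, j] = q``
for every *allowed* transition ``i -> j`` and 0 for forbidden ones
(Dollo-style constraints: a structure that cannot re-evolve simply has no
path back).  All allowed transitions share the single rate ``q``, which is
fitted by maximum likelihood with Felsenstein's pruning algorithm under a
flat root prior.

Per-node "scaled likelihoods" come in two flavours:

* ``conditional`` (default) -- the upward-pass conditional likelihood of
  the subtree below each node, normalized to sum to one.  This is what
  classic ML ancestral-state reconstructions report, and what the study
  this package reproduces plotted at its nodes.
* ``marginal`` -- the statistically preferred marginal reconstruction that
  combines the upward pass with the evidence from the rest of the tree.

The two agree at the root under a flat prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from araneae_pcm.treekit import PhyloTree, Node

__all__ = [
    "RateMatrixSpec", "MkFit", "AncestralEstimates", "build_q",
    "transition_probs", "pruning_loglik", "brute_force_loglik",
    "fit_mk_rate", "node_scaled_likelihoods",
]


@dataclass
class RateMatrixSpec:
    """Allowed-transition mask defining a one-parameter Mk model.

    ``allowed[i, j] = 1`` permits the transition from ``state_labels[i]``
    to ``state_labels[j]``; the diagonal is ignored.
    """

    state_labels: list[str]
    allowed: np.ndarray

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed)
        k = len(self.state_labels)
        if self.allowed.shape != (k, k):
            raise ValueError("allowed matrix must be square and match label count")
        off = ~np.eye(k, dtype=bool)
        vals = np.unique(self.allowed[off])
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("allowed entries must be 0 or 1")
        if self.allowed[off].sum() < 1:
            raise ValueError("at least one transition must be allowed")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise KeyError(
                f"state {label!r} not among {self.state_labels}"
            ) from None


@dataclass
class MkFit:
    rate: float
    loglik: float
    root_prior: np.ndarray
    converged: bool
    spec: RateMatrixSpec

    @property
    def loglik_sumroot(self) -> float:
        """``log sum_s L_root(s)`` -- the convention of the classic ML
        ancestral-state implementations, which report the root sum without
        the flat prior weight.  Differs from :attr:`loglik` by ``log k``
        when the prior is flat; this is the scale on which the study the
        package reproduces printed its log-likelihoods."""
        k = len(self.root_prior)
        if not np.allclose(self.root_prior, 1.0 / k):
            raise ValueError("sum-root scale is defined for the flat prior only")
        return float(self.loglik + np.log(k))


@dataclass
class AncestralEstimates:
    """Per-internal-node scaled state likelihoods (each row sums to 1).

    ``node_ids`` are stable preorder identifiers (``node0`` is the root);
    ``clades`` maps each id to the frozenset of descendant tip labels so
    nodes can be located without relying on traversal order.
    """

    state_labels: list[str]
    node_ids: list[str]
    likelihoods: np.ndarray
    clades: dict[str, frozenset[str]]

    def at_node(self, node_id: str) -> dict[str, float]:
        row = self.likelihoods[self.node_ids.index(node_id)]
        return dict(zip(self.state_labels, row.tolist()))

    def at_root(self) -> dict[str, float]:
        return self.at_node(self.node_ids[0])

    def at_mrca(self, tip_labels: set[str]) -> dict[str, float]:
        """Scaled likelihoods at the most recent common ancestor of the
        given tips (smallest clade containing all of them)."""
        candidates = [
            (len(clade), nid)
            for nid, clade in self.clades.items()
            if set(tip_labels) <= clade
        ]
        if not candidates:
            raise KeyError(f"no internal node contains all of {sorted(tip_labels)}")
        return self.at_node(min(candidates)[1])


def build_q(spec: RateMatrixSpec, rate: float) -> np.ndarray:
    """Generator matrix: ``rate`` on every allowed off-diagonal entry,
    diagonal set so rows sum to zero."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    Q = rate * spec.allowed.astype(float)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """``P(t) = expm(Q t)`` with entries clipped into [0, 1].

    scipy's scaling-and-squaring Pade implementation is robust for the
    asymmetric, frequently defective generators produced by constrained
    masks (absorbing rows, zero columns).
    """
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    k = Q.shape[0]
    if t == 0:
        return np.eye(k)
    P = expm(Q * t)
    P = np.clip(P, 0.0, 1.0)
    return P


def _resolve_root_prior(spec: RateMatrixSpec, root_prior) -> np.ndarray:
    k = spec.n_states
    if root_prior is None or (isinstance(root_prior, str) and root_prior == "flat"):
        return np.full(k, 1.0 / k)
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ValueError("root prior must be a length-k simplex vector")
    return pi


def _tip_likelihoods(
    tree: PhyloTree, tip_states: Mapping[str, str], spec: RateMatrixSpec
) -> dict[int, np.ndarray]:
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise ValueError(f"tips without states: {missing}")
    out: dict[int, np.ndarray] = {}
    for tip in tree.tips():
        vec = np.zeros(spec.n_states)
        vec[spec.index(tip_states[tip.label])] = 1.0
        out[id(tip)] = vec
    return out


def _propagator_family(spec: RateMatrixSpec):
    """Return a function ``P(rate, t)`` for the unit-rate generator.

    ``Q(rate) = rate * M`` with a fixed ``M``, so ``expm(Q t) =
    expm(M (rate t))`` depends on the product only.  When M is
    diagonalizable with a well-conditioned eigenbasis the exponential is
    evaluated through that basis (fast path used by the optimizer's many
    rate evaluations); otherwise fall back to scaling-and-squaring.
    """
    M = spec.allowed.astype(float).copy()
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, -M.sum(axis=1))
    use_eig = False
    try:
        w, U = np.linalg.eig(M)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) < 1e8:
            # accept the basis only if it reproduces expm on a test point
            P_eig = (U * np.exp(w)) @ Uinv
            if np.allclose(P_eig.real, expm(M), atol=1e-10):
                use_eig = True
    except np.linalg.LinAlgError:
        pass

    if use_eig:
        def propagate(rate: float, t: float) -> np.ndarray:
            P = ((U * np.exp(w * (rate * t))) @ Uinv).real
            return np.clip(P, 0.0, 1.0)
    else:
        def propagate(rate: float, t: float) -> np.ndarray:
            return transition_probs(build_q(spec, rate), t)

    return propagate


def _edge_probs(tree: PhyloTree, spec: RateMatrixSpec, rate: float) -> dict[int, np.ndarray]:
    propagate = _propagator_family(spec)
    # branch lengths repeat heavily on ultrametric fixtures; cache P(t)
    cache: dict[float, np.ndarray] = {}
    out: dict[int, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise ValueError(f"missing branch length above {node.label!r}")
        t = float(node.length)
        if t not in cache:
            cache[t] = propagate(rate, t)
        out[id(node)] = cache[t]
    return out


def _upward_pass(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    spec: RateMatrixSpec,
    rate: float,
):
    """Felsenstein pruning: conditional likelihoods at every node with
    per-node rescaling; returns (partials, log_scaler)."""
    tipL = _tip_likelihoods(tree, tip_states, spec)
    P = _edge_probs(tree, spec, rate)
    partial: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            partial[id(node)] = tipL[id(node)]
            continue
        L = np.ones(spec.n_states)
        for child in node.children:
            L = L * (P[id(child)] @ partial[id(child)])
        s = L.sum()
        if s <= 0:
            bad = _find_violating_tip(tree, node, tip_states)
            raise ValueError(
                "likelihood 0 under constrained matrix: no state at an "
                f"internal node can reach its descendant tips (e.g. tip {bad!r})"
            )
        if s < 1e-280:
            L = L / s
            log_scale += float(np.log(s))
        partial[id(node)] = L
    return partial, log_scale, P


def _find_violating_tip(tree: PhyloTree, node: Node, tip_states: Mapping[str, str]) -> str:
    def first_tip(n: Node) -> str:
        while not n.is_tip:
            n = n.children[0]
        return n.label  # type: ignore[return-value]

    return first_tip(node)


def pruning_loglik(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    spec: RateMatrixSpec,
    rate: float,
    root_prior="flat",
) -> float:
    """Log-likelihood of the tip states under the constrained Mk model."""
    pi = _resolve_root_prior(spec, root_prior)
    partial, log_scale, _ = _upward_pass(tree, tip_states, spec, rate)
    total = float(pi @ partial[id(tree.root)])
    if total <= 0:
        raise ValueError("likelihood 0 under constrained matrix at the root")
    return float(np.log(total) + log_scale)


def brute_force_loglik(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    spec: RateMatrixSpec,
    rate: float,
    root_prior="flat",
    max_internal: int = 12,
) -> float:
    """Likelihood by explicit enumeration of internal-state assignments.

    Exponential in the number of internal nodes; serves as the
    independent correctness oracle for :func:`pruning_loglik` on small
    trees.
    """
    internals = tree.internal_nodes()
    if len(internals) > max_internal:
        raise ValueError(f"too many internal nodes ({len(internals)}) for enumeration")
    pi = _resolve_root_prior(spec, root_prior)
    tipL = _tip_likelihoods(tree, tip_states, spec)
    P = _edge_probs(tree, spec, rate)
    k = spec.n_states
    total = 0.0
    for assignment in product(range(k), repeat=len(internals)):
        states = {id(n): s for n, s in zip(internals, assignment)}
        for tip in tree.tips():
            states[id(tip)] = int(np.argmax(tipL[id(tip)]))
        prob = pi[states[id(tree.root)]]
        for node in tree.preorder():
            if node is tree.root:
                continue
            prob *= P[id(node)][states[id(node.parent)], states[id(node)]]
            if prob == 0.0:
                break
        total += prob
    if total <= 0:
        raise ValueError("likelihood 0 under constrained matrix")
    return float(np.log(total))


def fit_mk_rate(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    spec: RateMatrixSpec,
    root_prior="flat",
    rate_bounds: tuple[float, float] | None = None,
) -> MkFit:
    """ML estimate of the single substitution rate by bounded 1-D search."""
    pi = _resolve_root_prior(spec, root_prior)
    depth = max(tree.depths().values())
    lo, hi = rate_bounds if rate_bounds is not None else (1e-8, 1000.0 / depth)

    def nll(rate: float) -> float:
        try:
            return -pruning_loglik(tree, tip_states, spec, rate, pi)
        except ValueError:
            return np.inf

    # the likelihood can be zero (nll infinite) over much of the rate
    # range under hard constraints, which derails bounded Brent; bracket
    # the optimum on a coarse log-spaced grid first
    grid = np.geomspace(lo, hi, 41)
    values = np.array([nll(r) for r in grid])
    if not np.any(np.isfinite(values)):
        raise ValueError("likelihood is zero for all rates: tip states are "
                         "unreachable under the constrained matrix")
    i = int(np.argmin(values))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        nll, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-10}
    )
    rate, ll = float(res.x), -float(res.fun)
    if values[i] < -ll:  # grid point beat the local search; keep it
        rate, ll = float(grid[i]), float(-values[i])
    return MkFit(rate=rate, loglik=ll, root_prior=pi, converged=bool(res.success), spec=spec)


def node_scaled_likelihoods(
    tree: PhyloTree,
    tip_states: Mapping[str, str],
    spec: RateMatrixSpec,
    fit: MkFit,
    mode: str = "conditional",
) -> AncestralEstimates:
    """Scaled state likelihoods for every internal node.

    ``conditional`` normalizes the upward-pass partials (what classic ML
    reconstructions report); ``marginal`` multiplies in the downward
    message so each node's vector conditions on all tips.  The two agree
    at the root when the prior is flat.
    """
    if mode not in ("conditional", "marginal"):
        raise ValueError("mode must be 'conditional' or 'marginal'")
    partial, _, P = _upward_pass(tree, tip_states, spec, fit.rate)

    internals = [n for n in tree.preorder() if not n.is_tip]
    if mode == "conditional":
        vectors = {id(n): partial[id(n)] / partial[id(n)].sum() for n in internals}
    else:
        # downward messages: root carries the prior; a child's message is
        # (parent message * siblings' upward contributions) pushed through
        # its own transition matrix.
        down: dict[int, np.ndarray] = {id(tree.root): fit.root_prior.copy()}
        for node in tree.preorder():
            if node.is_tip:
                continue
            for child in node.children:
                msg = down[id(node)].copy()
                for sib in node.children:
                    if sib is child:
                        continue
                    msg = msg * (P[id(sib)] @ partial[id(sib)])
                down[id(child)] = P[id(child)].T @ msg
        vectors = {}
        for n in internals:
            v = partial[id(n)] * down[id(n)]
            vectors[id(n)] = v / v.sum()

    node_ids = [f"node{i}" for i in range(len(internals))]
    clades = {
        nid: frozenset(
            t.label for t in tree.tips() if _is_descendant(t, node)
        )
        for nid, node in zip(node_ids, internals)
    }
    M = np.vstack([vectors[id(n)] for n in internals])
    return AncestralEstimates(
        state_labels=list(spec.state_labels),
        node_ids=node_ids,
        likelihoods=M,
        clades=clades,
    )


def _is_descendant(tip: Node, ancestor: Node) -> bool:
    n: Node | None = tip
    while n is not None:
        if n is ancestor:
            return True
        n = n.parent
    return False
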