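"""Seeded generators with the statistical structure the analyses assume.

Every stage of the pipeline is testable without external data: Yule
(pure-birth) trees supply topologies with branch lengths, Brownian motion
on those trees supplies continuous traits (optionally damped with Pagel's
lambda), and exact continuous-time Markov simulation supplies discrete
characters under arbitrary allowed-transition masks.

One global seed expands into per-component substreams through
``numpy.random.SeedSequence.spawn``, so a single integer reproduces the
full output stream of any composite simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from araneae_pcm.treekit import PhyloTree, Node, vcv_matrix, lambda_transform
from araneae_pcm.mkace import RateMatrixSpec

__all__ = [
    "SimConfig", "simulate_yule_tree", "simulate_bm", "simulate_mk",
    "simulate_regression_dataset",
]


@dataclass
class SimConfig:
    seed: int = 0
    n_tips: int = 50
    birth_rate: float = 1.0
    sigma2: float = 1.0
    lam: float = 1.0
    intercept: float = 0.0
    slopes: tuple[float, ...] = ()
    mk_rate: float = 1.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        for name in ("birth_rate", "sigma2", "mk_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed=None, prefix: str = "t"
) -> PhyloTree:
    """Pure-birth tree: start from two lineages, split a uniformly chosen
    lineage after an Exp(b * k) wait, stop at ``n_tips``; tip branches are
    extended to the final time so the tree is ultrametric."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)

    root = Node()
    active: list[Node] = []
    birth_time: dict[int, float] = {}
    for _ in range(2):
        c = Node(parent=root)
        root.children.append(c)
        active.append(c)
        birth_time[id(c)] = 0.0
    t = 0.0
    counter = 0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(int(idx))
        node.length = t - birth_time[id(node)]
        for _ in range(2):
            c = Node(parent=node)
            node.children.append(c)
            active.append(c)
            birth_time[id(c)] = t
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = t - birth_time[id(node)]
        node.label = f"{prefix}{counter}"
        counter += 1
    return PhyloTree(root)


def simulate_bm(
    tree: PhyloTree, sigma2: float = 1.0, lam: float = 1.0, seed=None
) -> dict[str, float]:
    """One multivariate-normal draw with covariance ``sigma2 * V(lam)``."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = _rng(seed)
    V = lambda_transform(vcv_matrix(tree), lam)
    n = len(V.labels)
    if sigma2 == 0:
        return {l: 0.0 for l in V.labels}
    # eigh-based square root: tolerant of the singular V that star-like
    # lambda transforms can produce
    w, U = np.linalg.eigh(sigma2 * V.matrix)
    w = np.clip(w, 0.0, None)
    y = U @ (np.sqrt(w) * rng.standard_normal(n))
    return dict(zip(V.labels, y.tolist()))


def simulate_mk(
    tree: PhyloTree,
    spec: RateMatrixSpec,
    rate: float,
    root_state: str,
    seed=None,
) -> dict[str, str]:
    """Exact CTMC simulation along every edge.

    In each state the waiting time is Exp(total exit rate); the jump
    target is chosen with probability proportional to the allowed rates.
    Absorbing states simply persist.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = _rng(seed)
    k = spec.n_states
    R = rate * spec.allowed.astype(float)
    np.fill_diagonal(R, 0.0)
    exit_rates = R.sum(axis=1)

    start = spec.index(root_state)
    states: dict[int, int] = {id(tree.root): start}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = states[id(node.parent)]
        remaining = float(node.length or 0.0)
        while exit_rates[s] > 0:
            wait = rng.exponential(1.0 / exit_rates[s])
            if wait > remaining:
                break
            remaining -= wait
            s = int(rng.choice(k, p=R[s] / exit_rates[s]))
        states[id(node)] = s
        if node.is_tip:
            out[node.label] = spec.state_labels[s]  # type: ignore[index]
    return out


def simulate_regression_dataset(
    tree: PhyloTree, config: SimConfig, seed=None
) -> pd.DataFrame:
    """Predictors + response with Brownian error for PGLS recovery tests.

    The first predictor is binary, produced by thresholding a Brownian
    trait at its median so that the predictor itself carries phylogenetic
    signal (the situation of the study's trait table); any further
    predictors are plain Brownian traits.  The response is
    ``intercept + X @ slopes + BM(sigma2)``.
    """
    n_pred = len(config.slopes)
    if n_pred < 1:
        raise ValueError("config.slopes must name at least one predictor slope")
    base = np.random.SeedSequence(config.seed if seed is None else seed)
    streams = base.spawn(n_pred + 1)
    labels = tree.tip_labels
    cols: dict[str, list[float]] = {}
    X = np.zeros((len(labels), n_pred))
    for j in range(n_pred):
        raw = simulate_bm(tree, 1.0, 1.0, np.random.default_rng(streams[j]))
        v = np.array([raw[l] for l in labels])
        if j == 0:
            v = (v > np.median(v)).astype(float)
        X[:, j] = v
        cols[f"x{j + 1}"] = v.tolist()
    noise = simulate_bm(tree, config.sigma2, config.lam,
                        np.random.default_rng(streams[n_pred]))
    e = np.array([noise[l] for l in labels])
    y = config.intercept + X @ np.asarray(config.slopes) + e
    frame = pd.DataFrame({"y": y, **cols}, index=labels)
    frame.index.name = "species"
    return frame
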