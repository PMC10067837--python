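"""Maximum-likelihood gene gain/loss reconstruction on a species tree.

Gene presence/absence evolves along the tree as a two-state
continuous-time Markov chain with gain rate ``g`` (absent -> present) and
loss rate ``l`` (present -> absent) per unit branch length. For a branch
of length ``t`` with ``r = g + l``::

    P(0->1) = (g/r) * (1 - exp(-r*t))
    P(1->0) = (l/r) * (1 - exp(-r*t))

Family likelihoods are computed by Felsenstein pruning, marginal
presence posteriors by the standard up-down (outside) recursion, and the
two rates by bounded quasi-Newton optimisation of the summed
log-likelihood with the root prior fixed at the stationary distribution.
Because families absent from every genome can never be observed as
clusters, the likelihood is by default conditioned on presence in at
least one leaf (ascertainment correction).

Per-edge gains and losses are called where the presence posterior
changes by more than a threshold (default 0.5, strict) between the
parent and child node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from skbio import TreeNode

from .core import PhyleticMatrix

_LOG_RATE_BOUND = 6.0  # rates constrained to [e^-6, e^6]


@dataclass
class GainLossModel:
    gain_rate: float
    loss_rate: float
    root_prior: float
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.root_prior <= 1.0:
            raise ValueError("root_prior must be in [0, 1]")

    @classmethod
    def with_stationary_prior(cls, gain_rate: float, loss_rate: float,
                              log_likelihood: float | None = None):
        r = gain_rate + loss_rate
        prior = gain_rate / r if r > 0 else 0.5
        return cls(gain_rate, loss_rate, prior, log_likelihood)


@dataclass(frozen=True)
class EventCall:
    family: str
    parent: str
    child: str
    kind: str  # "gain" | "loss"
    delta: float


def transition_probability(g: float, l: float, t: float) -> np.ndarray:
    """2x2 stochastic matrix of the two-state chain over time ``t``.

    Rows are the starting state (0 = absent, 1 = present).
    """
    if g < 0 or l < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    r = g + l
    if r == 0:
        warnings.warn("g + l = 0: transition matrix is the identity",
                      stacklevel=2)
        return np.eye(2)
    decay = 1.0 - np.exp(-r * t)
    p01 = (g / r) * decay
    p10 = (l / r) * decay
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# tree indexing


class _TreeIndex:
    """Array view of a rooted tree for vectorised pruning."""

    def __init__(self, tree: TreeNode):
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.names = [
            n.name if n.name is not None else f"_node{i}"
            for i, n in enumerate(self.nodes)
        ]
        self.root = len(self.nodes) - 1
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.lengths = np.array(
            [0.0 if n.length is None else float(n.length) for n in self.nodes]
        )
        self.leaf_indices = [
            i for i, n in enumerate(self.nodes) if n.is_tip()
        ]
        self.leaf_names = [self.names[i] for i in self.leaf_indices]
        missing = [
            self.names[i] for i in self.leaf_indices
            if self.nodes[i].name is None
        ]
        if missing:
            raise ValueError("tree has unnamed leaves")


def _leaf_patterns(index: _TreeIndex, patterns: pd.DataFrame) -> np.ndarray:
    """(n_fam, n_leaves) 0/1 array ordered like the tree's leaves."""
    missing = set(index.leaf_names) - set(patterns.columns)
    extra = set(patterns.columns) - set(index.leaf_names)
    if missing or extra:
        raise ValueError(
            f"pattern genomes do not match tree leaves "
            f"(missing={sorted(missing)}, extra={sorted(extra)})"
        )
    return (patterns[index.leaf_names].to_numpy() >= 1).astype(float)


def _pruning(
    index: _TreeIndex, leaf01: np.ndarray, model: GainLossModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Post-order partial likelihoods with per-family scaling.

    Returns (D, logscale, P) where D[i] is the (n_fam, 2) scaled partial
    likelihood at node i, logscale the accumulated per-family log scale,
    and P[i] the transition matrix over node i's parent edge.
    """
    n_fam = leaf01.shape[0]
    n_nodes = len(index.nodes)
    P = np.empty((n_nodes, 2, 2))
    for i in range(n_nodes):
        P[i] = transition_probability(
            model.gain_rate, model.loss_rate, index.lengths[i]
        ) if i != index.root else np.eye(2)
    D = np.empty((n_nodes, n_fam, 2))
    logscale = np.zeros(n_fam)
    leaf_pos = {li: k for k, li in enumerate(index.leaf_indices)}
    for i, node in enumerate(index.nodes):
        if not index.children[i]:
            obs = leaf01[:, leaf_pos[i]]
            D[i, :, 0] = 1.0 - obs
            D[i, :, 1] = obs
        else:
            acc = np.ones((n_fam, 2))
            for c in index.children[i]:
                acc *= D[c] @ P[c].T
            scale = acc.max(axis=1)
            safe = np.where(scale > 0, scale, 1.0)
            D[i] = acc / safe[:, None]
            logscale += np.where(scale > 0, np.log(safe), -np.inf)
    return D, logscale, P


def _log_likelihoods(
    index: _TreeIndex,
    leaf01: np.ndarray,
    model: GainLossModel,
    ascertainment: bool,
) -> np.ndarray:
    D, logscale, _ = _pruning(index, leaf01, model)
    prior = np.array([1.0 - model.root_prior, model.root_prior])
    lik = D[index.root] @ prior
    with np.errstate(divide="ignore"):
        logl = np.log(lik) + logscale
    if ascertainment:
        # P(observed) = 1 - P(all leaves absent)
        absent = np.zeros((1, leaf01.shape[1]))
        D0, ls0, _ = _pruning(index, absent, model)
        l0 = float((D0[index.root] @ prior)[0] * np.exp(ls0[0]))
        logl = logl - np.log1p(-l0)
    return logl


def pattern_likelihood(
    tree: TreeNode,
    pattern,
    model: GainLossModel,
    ascertainment: bool = False,
) -> float:
    """Likelihood of one presence/absence pattern (mapping leaf -> 0/1)."""
    index = _TreeIndex(tree)
    df = pd.DataFrame([dict(pattern)])
    leaf01 = _leaf_patterns(index, df)
    logl = _log_likelihoods(index, leaf01, model, ascertainment)
    return float(np.exp(logl[0]))


def fit_rates(
    matrix: PhyleticMatrix,
    tree: TreeNode,
    ascertainment: bool = True,
) -> GainLossModel:
    """ML estimate of (gain, loss) with the root prior at stationarity.

    Optimises the summed (ascertainment-corrected) log-likelihood of all
    family patterns over log-rates bounded in [-6, 6]; the deterministic
    start is g = l = 1.
    """
    index = _TreeIndex(tree)
    leaf01 = _leaf_patterns(index, matrix.binarized())
    patterns, counts = np.unique(leaf01, axis=0, return_counts=True)
    if patterns.shape[0] == 1 and patterns.min() == 1.0:
        warnings.warn(
            "all families present everywhere: loss rate hits the lower "
            "bound", stacklevel=2
        )

    def negloglik(logrates: np.ndarray) -> float:
        g, l = np.exp(logrates)
        model = GainLossModel.with_stationary_prior(g, l)
        logl = _log_likelihoods(index, patterns, model, ascertainment)
        return -float(np.dot(counts, logl))

    res = minimize(
        negloglik,
        x0=np.zeros(2),
        method="L-BFGS-B",
        bounds=[(-_LOG_RATE_BOUND, _LOG_RATE_BOUND)] * 2,
    )
    g, l = np.exp(res.x)
    return GainLossModel.with_stationary_prior(
        float(g), float(l), log_likelihood=-float(res.fun)
    )


def marginal_posteriors(
    tree: TreeNode,
    matrix: PhyleticMatrix | pd.DataFrame,
    model: GainLossModel,
) -> pd.DataFrame:
    """P(present | pattern, model) for every family at every node.

    Returns a DataFrame indexed by family with one column per tree node
    (named; leaves keep their observed 0/1 state).
    """
    if isinstance(matrix, PhyleticMatrix):
        patterns = matrix.binarized()
    else:
        patterns = (matrix >= 1).astype(int)
    index = _TreeIndex(tree)
    leaf01 = _leaf_patterns(index, patterns)
    D, _, P = _pruning(index, leaf01, model)
    n_fam = leaf01.shape[0]
    n_nodes = len(index.nodes)
    prior = np.array([1.0 - model.root_prior, model.root_prior])
    U = np.empty((n_nodes, n_fam, 2))
    U[index.root] = prior
    # pre-compute each node's message to its parent
    M = np.empty((n_nodes, n_fam, 2))
    for i in range(n_nodes):
        if i != index.root:
            M[i] = D[i] @ P[i].T
    for i in reversed(range(n_nodes)):  # root first (postorder reversed)
        for c in index.children[i]:
            sib = U[i].copy()
            for s in index.children[i]:
                if s != c:
                    sib *= M[s]
            U[c] = sib @ P[c]
            norm = U[c].sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            U[c] /= norm
    post = np.empty((n_fam, n_nodes))
    for i in range(n_nodes):
        joint = U[i] * D[i]
        total = joint.sum(axis=1)
        safe = np.where(total > 0, total, 1.0)
        post[:, i] = joint[:, 1] / safe
    return pd.DataFrame(post, index=list(patterns.index),
                        columns=index.names)


def call_events(
    posteriors: pd.DataFrame,
    tree: TreeNode,
    threshold: float = 0.5,
) -> list[EventCall]:
    """Per-edge gain/loss calls where the posterior change is strictly
    greater than ``threshold`` in magnitude; sorted by (family, child)."""
    calls: list[EventCall] = []
    edges = [
        (n.parent.name, n.name)
        for n in tree.preorder(include_self=False)
    ]
    for fam in posteriors.index:
        row = posteriors.loc[fam]
        for parent, child in edges:
            delta = float(row[child] - row[parent])
            if delta > threshold:
                calls.append(EventCall(fam, parent, child, "gain", delta))
            elif delta < -threshold:
                calls.append(EventCall(fam, parent, child, "loss", delta))
    calls.sort(key=lambda e: (e.family, e.child))
    return calls


def ancestral_content_size(
    node: str, posteriors: pd.DataFrame
) -> tuple[int, float]:
    """Expected number of families present at ``node``: (rounded, raw)."""
    if node not in posteriors.columns:
        raise ValueError(f"unknown node {node!r}")
    raw = float(posteriors[node].sum())
    return int(round(raw)), raw


@dataclass
class GainLossResult:
    model: GainLossModel
    posteriors: pd.DataFrame
    events: list[EventCall]
    ancestral_content: pd.Series  # node -> expected family count


def reconstruct(
    matrix: PhyleticMatrix,
    tree: TreeNode,
    model: GainLossModel | None = None,
    threshold: float = 0.5,
    ascertainment: bool = True,
) -> GainLossResult:
    """Fit (unless given), compute posteriors, call events, and sum
    ancestral genome content at every node."""
    if model is None:
        model = fit_rates(matrix, tree, ascertainment=ascertainment)
    post = marginal_posteriors(tree, matrix, model)
    events = call_events(post, tree, threshold=threshold)
    content = pd.Series(
        {node: post[node].sum() for node in post.columns}, dtype=float
    )
    return GainLossResult(model, post, events, content)
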