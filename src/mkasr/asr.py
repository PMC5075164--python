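"""Ancestral state inference on a single tree.

Two reconstructions are provided for a fitted Q:

* :func:`marginal_asr` — for each node, the posterior probability of each
  state given all tip data (computed by combining upward conditional
  likelihoods with downward "outside" messages; equivalent to re-rooting
  the pruning pass at every node).
* :func:`simmap` — stochastic character mapping: full character histories
  (joint node states plus per-branch piecewise-constant state paths)
  sampled from their exact conditional distribution given the tip data.
  Branch paths are endpoint-conditioned CTMC draws obtained by
  uniformisation with dominating rate Lambda = max_i |Q_ii|.

Q is treated as fixed (typically at its per-tree MLE), i.e. an empirical
Bayes reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mk import MISSING, QMatrix, TipStates, _pruning, _QPropagator
from .treeio import PhyloTree

__all__ = [
    "NodeMarginals",
    "SimmapHistory",
    "marginal_asr",
    "sample_branch_history",
    "simmap",
    "most_likely_state",
]

log = logging.getLogger(__name__)


@dataclass
class NodeMarginals:
    """Per-node state probability vectors (rows sum to 1)."""

    probs: np.ndarray  # (n_nodes, k)
    method: str  # "marginal-ML" | "simmap-frequency"
    n_draws: int | None = None

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    def __getitem__(self, node: int) -> np.ndarray:
        return self.probs[node]


@dataclass
class SimmapHistory:
    """One sampled character history on one tree.

    ``node_states[v]`` is the sampled state at node v.  ``branch_paths[v]``
    is the path along the branch above v as ordered (duration, state)
    segments running from the parent end to v; durations sum to the
    branch length and adjacent segments differ in state.
    """

    node_states: np.ndarray
    branch_paths: dict[int, list[tuple[float, int]]] = field(default_factory=dict)

    def n_changes(self) -> int:
        return sum(len(p) - 1 for p in self.branch_paths.values())


# ---------------------------------------------------------------------------
# marginal reconstruction


def marginal_asr(
    tree: PhyloTree,
    tips: TipStates,
    q: QMatrix,
    root_prior: np.ndarray | None = None,
) -> NodeMarginals:
    """Marginal posterior state probabilities at every node."""
    if root_prior is None:
        root_prior = np.full(q.k, 1.0 / q.k)
    root_prior = np.asarray(root_prior, dtype=float)
    up, _, P = _pruning(tree, tips, q)
    out = np.zeros_like(up)
    out[0] = root_prior
    # preorder: parents before children
    for v in tree.postorder()[::-1]:
        kids = tree.children[v]
        if not kids:
            continue
        msgs = [P[c] @ up[c] for c in kids]  # child messages at v
        for idx, c in enumerate(kids):
            sib = out[v].copy()
            for jdx, m in enumerate(msgs):
                if jdx != idx:
                    sib *= m
            oc = P[c].T @ sib
            tot = oc.sum()
            out[c] = oc / tot if tot > 0 else np.full(q.k, 1.0 / q.k)
    marg = out * up
    tot = marg.sum(axis=1, keepdims=True)
    bad = ~np.isfinite(tot[:, 0]) | (tot[:, 0] <= 0)
    if np.any(bad):
        raise ValueError("zero-probability data; marginals undefined at some node")
    return NodeMarginals(probs=marg / tot, method="marginal-ML")


def most_likely_state(marginals: NodeMarginals, node: int) -> int:
    """Argmax state at a node; ties break toward the lowest code (logged)."""
    p = marginals[node]
    best = int(np.argmax(p))
    ties = np.flatnonzero(np.isclose(p, p[best], rtol=0, atol=1e-12))
    if len(ties) > 1:
        log.warning("state tie at node %d (%s); keeping state %d", node, p, ties[0])
        best = int(ties[0])
    return best


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling (uniformisation)


def _uniformized(q: QMatrix) -> tuple[float, np.ndarray]:
    lam = q.dominating_rate
    if lam <= 0:
        return 0.0, np.eye(q.k)
    return lam, np.eye(q.k) + q.matrix / lam


def sample_branch_history(
    t: float,
    start: int,
    end: int,
    q: QMatrix,
    rng: np.random.Generator,
    p_t: np.ndarray | None = None,
) -> list[tuple[float, int]]:
    """Sample one endpoint-conditioned CTMC path over a branch.

    Returns ordered (duration, state) segments from the parent end (state
    ``start``) to the child end (state ``end``).  Uses uniformisation: the
    number of candidate jumps is Poisson(Lambda*t) reweighted by the jump
    chain, jump times are order statistics of uniforms, and jump states
    are sampled by backward conditioning; self-jumps are collapsed.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    lam, R = _uniformized(q)
    lt = lam * t
    if lt < 1e-8:
        if start != end:
            raise ValueError(
                f"endpoint pair {start}->{end} impossible on branch of length {t}"
            )
        return [(t, start)]
    if p_t is None:
        from .mk import transition_probs

        p_t = transition_probs(q, t)
    p_ab = float(p_t[start, end])
    if p_ab <= 0:
        raise ValueError(f"endpoint pair {start}->{end} has probability 0")

    # sample the number of uniformised jumps n
    u = rng.random()
    rpow = [np.eye(q.k)]  # R^0
    log_pois = -lt
    cum = 0.0
    n = 0
    weight = np.exp(log_pois) * rpow[0][start, end] / p_ab
    cum += weight
    while cum <= u and cum < 1.0 - 1e-10:
        n += 1
        rpow.append(rpow[-1] @ R)
        log_pois += np.log(lt) - np.log(n)
        cum += np.exp(log_pois) * rpow[n][start, end] / p_ab
        if n > 100000:
            raise RuntimeError("uniformisation failed to terminate")
    # jump times and states
    times = np.sort(rng.random(n)) * t
    states = [start]
    s = start
    for i in range(1, n + 1):
        w = R[s, :] * rpow[n - i][:, end]
        w = w / w.sum()
        s = int(rng.choice(q.k, p=w))
        states.append(s)
    # collapse virtual (self) jumps into segments
    segs: list[tuple[float, int]] = []
    prev_time = 0.0
    cur = start
    for i in range(1, n + 1):
        if states[i] != cur:
            segs.append((times[i - 1] - prev_time, cur))
            prev_time = times[i - 1]
            cur = states[i]
    segs.append((t - prev_time, cur))
    assert cur == end
    return segs


# ---------------------------------------------------------------------------
# stochastic mapping over a tree


def _sample_joint_node_states(
    tree: PhyloTree,
    up: np.ndarray,
    P: np.ndarray,
    root_prior: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_draws, n_nodes) joint node-state draws from the conditional
    distribution given tip data (root first, then child given parent)."""
    k = up.shape[1]
    states = np.empty((n_draws, tree.n_nodes), dtype=np.int64)
    w0 = root_prior * up[0]
    tot = w0.sum()
    if tot <= 0:
        raise ValueError("zero-probability data at root")
    cdf = np.cumsum(w0 / tot)
    states[:, 0] = np.searchsorted(cdf, rng.random(n_draws), side="right")
    for v in tree.postorder()[::-1]:  # preorder
        for c in tree.children[v]:
            w = P[c][states[:, v], :] * up[c][None, :]  # (n_draws, k)
            w_sum = w.sum(axis=1, keepdims=True)
            if np.any(w_sum <= 0):
                raise ValueError("zero-probability transition while sampling")
            cdfs = np.cumsum(w / w_sum, axis=1)
            u = rng.random(n_draws)
            states[:, c] = (cdfs < u[:, None]).sum(axis=1)
    np.clip(states, 0, k - 1, out=states)
    return states


def simmap(
    tree: PhyloTree,
    tips: TipStates,
    q: QMatrix,
    n_draws: int,
    rng: np.random.Generator,
    root_prior: np.ndarray | None = None,
    include_histories: bool = True,
) -> tuple[list[SimmapHistory], NodeMarginals]:
    """Stochastic character mapping.

    Each draw first samples the joint node states from their exact
    conditional distribution, then (when ``include_histories``) fills in
    every branch with an endpoint-conditioned path.  ``node_freqs`` are
    the empirical per-node state frequencies across draws.  Observed tips
    keep their observed state; missing-state tips are sampled like
    internal nodes.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if root_prior is None:
        root_prior = np.full(q.k, 1.0 / q.k)
    root_prior = np.asarray(root_prior, dtype=float)
    up, _, P = _pruning(tree, tips, q)
    states = _sample_joint_node_states(tree, up, P, root_prior, n_draws, rng)

    histories: list[SimmapHistory] = []
    if include_histories:
        prop = _QPropagator(q)
        p_cache: dict[float, np.ndarray] = {}
        for d in range(n_draws):
            paths: dict[int, list[tuple[float, int]]] = {}
            for v in range(1, tree.n_nodes):
                t = float(tree.blen[v])
                if t not in p_cache:
                    p_cache[t] = prop.probs(np.array([t]))[0]
                paths[v] = sample_branch_history(
                    t,
                    int(states[d, int(tree.parent[v])]),
                    int(states[d, v]),
                    q,
                    rng,
                    p_t=p_cache[t],
                )
            histories.append(SimmapHistory(node_states=states[d].copy(), branch_paths=paths))
    else:
        histories = [SimmapHistory(node_states=states[d].copy()) for d in range(n_draws)]

    freqs = np.zeros((tree.n_nodes, q.k))
    for s in range(q.k):
        freqs[:, s] = (states == s).mean(axis=0)
    node_freqs = NodeMarginals(probs=freqs, method="simmap-frequency", n_draws=n_draws)
    return histories, node_freqs
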