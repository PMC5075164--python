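"""Mk (continuous-time Markov) models for discrete characters on trees.

The Mk model assigns a k-state character an instantaneous rate matrix Q
(rows sum to zero, off-diagonals >= 0) and evolves it independently along
each branch, so the transition matrix over a branch of length t is
P(t) = exp(Qt).  Three standard parameterisations are supported:

* ER  — equal rates: one rate shared by all transitions;
* SYM — symmetric rates: q_ij = q_ji, k(k-1)/2 parameters;
* ARD — all rates different: k(k-1) parameters.

For binary characters SYM is identical to ER and is collapsed to ER.

Likelihoods are computed with the pruning algorithm (post-order dynamic
programming over conditional likelihood vectors), with per-node rescaling
to avoid underflow.  Fitting maximises the log-likelihood over log-rates
with a bounded quasi-Newton optimiser and a small number of deterministic
restarts.  Model selection uses AIC with a "simpler model preferred"
tie rule.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize

from .treeio import PhyloTree

__all__ = [
    "ModelClass",
    "QMatrix",
    "TipStates",
    "MkFit",
    "MISSING",
    "build_q",
    "q_to_params",
    "transition_probs",
    "transition_probs_many",
    "mk_loglik",
    "fit_mk",
    "select_model",
    "candidate_models",
    "transition_labels",
    "rates_by_transition",
]

MISSING = -1

# optimiser bounds on each rate (events per unit branch length)
RATE_LO = 1e-8
RATE_HI = 1e3


class ModelClass(str, enum.Enum):
    ER = "ER"
    SYM = "SYM"
    ARD = "ARD"

    def n_params(self, k: int) -> int:
        if self is ModelClass.ER:
            return 1
        if self is ModelClass.SYM:
            return k * (k - 1) // 2
        return k * (k - 1)


@dataclass(frozen=True)
class QMatrix:
    """Validated instantaneous rate matrix."""

    k: int
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.k, self.k):
            raise ValueError(f"Q must be {self.k}x{self.k}")
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(m.sum(axis=1), 0.0, atol=1e-9):
            raise ValueError("Q rows must sum to 0")
        object.__setattr__(self, "matrix", m)

    @property
    def dominating_rate(self) -> float:
        """Lambda = max_i |Q_ii|, the uniformisation rate."""
        return float(np.max(-np.diag(self.matrix)))


@dataclass
class TipStates:
    """Observed tip states for one character.

    ``states`` maps tip label to a state code ``0..k-1`` or :data:`MISSING`.
    ``state_names`` maps code to a display name.
    """

    k: int
    states: dict[str, int]
    state_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for lab, s in self.states.items():
            if s != MISSING and not 0 <= s < self.k:
                raise ValueError(f"tip {lab!r}: state code {s} out of range for k={self.k}")
        if not self.state_names:
            self.state_names = {i: str(i) for i in range(self.k)}

    def observed_labels(self) -> list[str]:
        return [l for l, s in self.states.items() if s != MISSING]

    def observed_state_codes(self) -> set[int]:
        return {s for s in self.states.values() if s != MISSING}


@dataclass
class MkFit:
    model_class: ModelClass
    k: int
    rate_params: np.ndarray
    logL: float
    root_prior: np.ndarray
    converged: bool
    n_restarts_used: int

    @property
    def n_params(self) -> int:
        return self.model_class.n_params(self.k)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.logL

    @property
    def q(self) -> QMatrix:
        return build_q(self.model_class, self.k, self.rate_params)


# ---------------------------------------------------------------------------
# Q construction


def _sym_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def _ard_pairs(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def build_q(model_class: ModelClass, k: int, params: Sequence[float]) -> QMatrix:
    """Build the rate matrix for a model class from its free parameters.

    SYM fills q_ij = q_ji in lexicographic (i<j) order; ARD fills in
    row-major order skipping the diagonal.
    """
    model_class = ModelClass(model_class)
    params = np.asarray(params, dtype=float)
    expect = model_class.n_params(k)
    if params.shape != (expect,):
        raise ValueError(
            f"{model_class.value} with k={k} needs {expect} rate(s), got {params.shape}"
        )
    if np.any(params < 0):
        raise ValueError("rates must be >= 0")
    m = np.zeros((k, k))
    if model_class is ModelClass.ER:
        m[:] = params[0]
    elif model_class is ModelClass.SYM:
        for r, (i, j) in zip(params, _sym_pairs(k)):
            m[i, j] = m[j, i] = r
    else:
        for r, (i, j) in zip(params, _ard_pairs(k)):
            m[i, j] = r
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=1))
    return QMatrix(k, m)


def q_to_params(model_class: ModelClass, q: QMatrix) -> np.ndarray:
    """Inverse of :func:`build_q` (reads rates off Q in canonical order)."""
    m = q.matrix
    if model_class is ModelClass.ER:
        return np.array([m[0, 1]])
    if model_class is ModelClass.SYM:
        return np.array([m[i, j] for i, j in _sym_pairs(q.k)])
    return np.array([m[i, j] for i, j in _ard_pairs(q.k)])


def transition_labels(k: int) -> list[str]:
    """Directional transition labels in reporting order ("0 to 1", ...)."""
    return [f"{i} to {j}" for i, j in _ard_pairs(k)]


def rates_by_transition(q: QMatrix) -> dict[str, float]:
    return {f"{i} to {j}": float(q.matrix[i, j]) for i, j in _ard_pairs(q.k)}


# ---------------------------------------------------------------------------
# transition probabilities


class _QPropagator:
    """Eigendecomposition-backed computation of P(t) = exp(Qt).

    Falls back to scipy's Pade/scaling-squaring expm when the
    eigendecomposition is ill-conditioned (defective Q).
    """

    def __init__(self, q: "QMatrix | np.ndarray"):
        mat = q.matrix if isinstance(q, QMatrix) else np.asarray(q, dtype=float)
        self.matrix = mat
        self.k = mat.shape[0]
        self._ok = False
        try:
            w, v = np.linalg.eig(mat)
            vinv = np.linalg.inv(v)
            # cheap health check in place of a condition number: the
            # decomposition must reproduce Q itself
            err = np.abs((v * w) @ vinv - mat).max()
            scale = max(1.0, np.abs(mat).max())
            if np.isfinite(err) and err < 1e-9 * scale:
                self.w, self.v, self.vinv = w, v, vinv
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def probs(self, t: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths; shape (len(t), k, k)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch lengths must be >= 0")
        if self._ok:
            ew = np.exp(np.multiply.outer(t, self.w))  # (n, k)
            p = np.einsum("ij,nj,jk->nik", self.v, ew, self.vinv)
            p = np.real(p)
        else:
            p = np.stack([scipy.linalg.expm(self.matrix * ti) for ti in t])
        np.clip(p, 0.0, 1.0, out=p)
        p /= p.sum(axis=2, keepdims=True)
        p[t == 0] = np.eye(self.k)  # exact identity, not eig round-off
        return p


def transition_probs(q: QMatrix, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = exp(Qt) for one branch length."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    return _QPropagator(q).probs(np.array([t]))[0]


def transition_probs_many(q: QMatrix, t: np.ndarray) -> np.ndarray:
    return _QPropagator(q).probs(t)


# ---------------------------------------------------------------------------
# pruning likelihood


def _tip_partials(tree: PhyloTree, tips: TipStates) -> np.ndarray:
    """(n_nodes, k) array; tip rows are indicator (or all-ones) vectors."""
    k = tips.k
    part = np.ones((tree.n_nodes, k))
    for v in tree.tip_indices:
        lab = tree.label[v]
        if lab not in tips.states:
            raise ValueError(f"tree tip {lab!r} has no entry in TipStates")
        s = tips.states[lab]
        if s != MISSING:
            part[v, :] = 0.0
            part[v, s] = 1.0
    return part


def _pruning_from_partials(
    tree: PhyloTree, tip_part: np.ndarray, prop: _QPropagator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Post-order conditional likelihoods with rescaling.

    Returns (partials, log_scalers, P) where ``partials[v]`` is the
    rescaled conditional likelihood of the data below node v given the
    state at v, ``log_scalers[v]`` the accumulated log scaling factor for
    the subtree, and ``P[v]`` the transition matrix along v's branch.
    """
    k = prop.k
    P = prop.probs(tree.blen)
    part = tip_part.copy()
    logsc = np.zeros(tree.n_nodes)
    # vectorised post-order: one level of internal nodes at a time
    with np.errstate(divide="ignore", invalid="ignore"):
        for nodes, child_ids, starts in tree.levels():
            msgs = np.einsum("nij,nj->ni", P[child_ids], part[child_ids])
            acc = np.multiply.reduceat(msgs, starts, axis=0)
            s = np.add.reduceat(logsc[child_ids], starts)
            m = acc.max(axis=1)
            dead = m <= 0.0
            part[nodes] = acc / np.where(dead, 1.0, m)[:, None]
            logsc[nodes] = s + np.where(dead, -np.inf, np.log(np.where(dead, 1.0, m)))
            if dead.any():  # data impossible below these nodes
                part[nodes[dead]] = 1.0 / k
    return part, logsc, P


def _pruning(
    tree: PhyloTree, tips: TipStates, q: QMatrix, propagator: _QPropagator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return _pruning_from_partials(
        tree, _tip_partials(tree, tips), propagator or _QPropagator(q)
    )


def mk_loglik(
    tree: PhyloTree,
    tips: TipStates,
    q: QMatrix,
    root_prior: np.ndarray | None = None,
) -> float:
    """Log-likelihood of tip states under Q by the pruning algorithm."""
    if root_prior is None:
        root_prior = np.full(q.k, 1.0 / q.k)
    root_prior = np.asarray(root_prior, dtype=float)
    if root_prior.shape != (q.k,) or not np.isclose(root_prior.sum(), 1.0):
        raise ValueError("root prior must be a length-k probability vector")
    part, logsc, _ = _pruning(tree, tips, q)
    lik = float(root_prior @ part[0])
    if lik <= 0.0 or not np.isfinite(logsc[0]):
        return -np.inf
    return float(np.log(lik) + logsc[0])


# ---------------------------------------------------------------------------
# fitting


def _stationary(q: "QMatrix | np.ndarray") -> np.ndarray:
    mat = q.matrix if isinstance(q, QMatrix) else np.asarray(q, dtype=float)
    w, v = np.linalg.eig(mat.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _root_prior(mode: str, q: "QMatrix | np.ndarray", k: int) -> np.ndarray:
    if mode == "uniform":
        return np.full(k, 1.0 / k)
    if mode == "stationary":
        return _stationary(q)
    raise ValueError(f"unknown root prior mode {mode!r}")


def _param_positions(model_class: ModelClass, k: int):
    """(row, col, param-index) arrays filling Q's off-diagonals."""
    rows, cols, pidx = [], [], []
    if model_class is ModelClass.ER:
        for i, j in _ard_pairs(k):
            rows.append(i), cols.append(j), pidx.append(0)
    elif model_class is ModelClass.SYM:
        for p, (i, j) in enumerate(_sym_pairs(k)):
            rows += [i, j]
            cols += [j, i]
            pidx += [p, p]
    else:
        for p, (i, j) in enumerate(_ard_pairs(k)):
            rows.append(i), cols.append(j), pidx.append(p)
    return np.array(rows), np.array(cols), np.array(pidx)


def _initial_rate(tree: PhyloTree, tips: TipStates) -> float:
    """Crude rate scale: one expected change over the total tree length."""
    total = float(tree.blen.sum())
    return 1.0 / max(total, 1e-6)


def fit_mk(
    tree: PhyloTree,
    tips: TipStates,
    model_class: ModelClass,
    root_prior_mode: str = "uniform",
    n_restarts: int = 3,
) -> MkFit:
    """Maximum-likelihood fit of an Mk model class.

    Rates are optimised on the log scale within [1e-8, 1e3] per rate with
    L-BFGS-B.  The starting scale comes from a coarse log-grid scan of
    the equal-rates likelihood (the surface saturates for large rates, so
    a gradient path started far from the optimum can stall on the
    plateau); restarts then launch from dispersed deterministic multiples
    of the grid optimum and the best log-likelihood is kept.
    ``converged`` is False when no restart converged; a fit is always
    returned.
    """
    model_class = ModelClass(model_class)
    k = tips.k
    if model_class is ModelClass.SYM and k == 2:
        model_class = ModelClass.ER  # identical likelihood surface
    npar = model_class.n_params(k)
    base = _initial_rate(tree, tips)
    lo, hi = np.log(RATE_LO), np.log(RATE_HI)
    tip_part = _tip_partials(tree, tips)
    rows, cols, pidx = _param_positions(model_class, k)

    def neg(logp: np.ndarray) -> float:
        m = np.zeros((k, k))
        m[rows, cols] = np.exp(logp)[pidx]
        np.fill_diagonal(m, -m.sum(axis=1))
        prior = _root_prior(root_prior_mode, m, k)
        part, logsc, _ = _pruning_from_partials(tree, tip_part, _QPropagator(m))
        lik = float(prior @ part[0])
        if lik <= 0.0 or not np.isfinite(logsc[0]):
            return 1e12
        return -(np.log(lik) + logsc[0])

    # coarse scan over the shared-rate scale to find the right basin
    grid = np.exp(np.linspace(np.log(base * 1e-3), np.log(min(base * 1e4, RATE_HI)), 22))
    grid_best = min(grid, key=lambda r: neg(np.full(npar, np.log(r))))

    # dispersed, deterministic multiplicative offsets around the grid optimum
    offsets = [1.0, 10.0, 0.1, 100.0, 0.01]
    best = None
    converged = False
    used = 0
    for mult in offsets[: max(1, n_restarts)]:
        used += 1
        x0 = np.full(npar, np.clip(np.log(grid_best * mult), lo, hi))
        res = scipy.optimize.minimize(
            neg,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * npar,
            options={"maxiter": 100, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    rates = np.exp(best.x)
    q = build_q(model_class, k, rates)
    prior = _root_prior(root_prior_mode, q, k)
    return MkFit(
        model_class=model_class,
        k=k,
        rate_params=rates,
        logL=float(mk_loglik(tree, tips, q, prior)),
        root_prior=prior,
        converged=converged,
        n_restarts_used=used,
    )


_COMPLEXITY = {ModelClass.ER: 0, ModelClass.SYM: 1, ModelClass.ARD: 2}


def candidate_models(k: int) -> list[ModelClass]:
    """ER/SYM/ARD, with SYM dropped for binary characters (SYM == ER)."""
    if k == 2:
        return [ModelClass.ER, ModelClass.ARD]
    return [ModelClass.ER, ModelClass.SYM, ModelClass.ARD]


def select_model(
    tree: PhyloTree,
    tips: TipStates,
    candidates: Sequence[ModelClass] | None = None,
    tie_margin: float = 0.0,
    root_prior_mode: str = "uniform",
    n_restarts: int = 3,
) -> tuple[MkFit, list[MkFit]]:
    """Fit candidate model classes and choose one by AIC.

    The minimum-AIC model wins, except that a more complex model whose
    AIC advantage over a simpler candidate is <= ``tie_margin`` loses to
    the simpler one (the simpler model is preferred when it cannot be
    rejected).  Returns (chosen fit, all fits in candidate order).
    """
    if candidates is None:
        candidates = candidate_models(tips.k)
    cands = [ModelClass(c) for c in candidates]
    if tips.k == 2:
        cands = [c for c in cands if c is not ModelClass.SYM]
    cands = sorted(set(cands), key=_COMPLEXITY.get)
    fits = [
        fit_mk(tree, tips, c, root_prior_mode=root_prior_mode, n_restarts=n_restarts)
        for c in cands
    ]
    chosen = fits[0]
    for f in fits[1:]:
        # f is more complex than current choice; it must beat the chosen
        # simpler model by more than tie_margin to displace it
        if f.aic < chosen.aic - tie_margin:
            chosen = f
    return chosen, fits


# ---------------------------------------------------------------------------
# brute-force oracle (exported for tests and cross-checks)


def loglik_enumeration(
    tree: PhyloTree,
    tips: TipStates,
    q: QMatrix,
    root_prior: np.ndarray | None = None,
) -> float:
    """Likelihood by explicit summation over all internal-node state
    assignments.  Exponential in the number of internal nodes; a test
    oracle, not a production path."""
    if root_prior is None:
        root_prior = np.full(q.k, 1.0 / q.k)
    P = transition_probs_many(q, tree.blen)
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_part = _tip_partials(tree, tips)
    total = 0.0
    for combo in itertools.product(range(q.k), repeat=len(internal)):
        state = dict(zip(internal, combo))
        p = root_prior[state[0]]
        for v in range(1, tree.n_nodes):
            sp = state[int(tree.parent[v])]
            if tree.is_tip(v):
                p *= float(P[v][sp] @ tip_part[v])
            else:
                p *= float(P[v][sp, state[v]])
        total += p
    return float(np.log(total)) if total > 0 else -np.inf
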