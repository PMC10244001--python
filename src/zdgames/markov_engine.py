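"""Long-run outcome distributions and payoffs for memory-one strategy pairs.

A memory-one strategy is a vector ``p = [p1, p2, p3, p4]`` of cooperation
probabilities conditioned on the previous round's outcome (CC, CD, DC, DD),
written from the strategy owner's perspective (first letter = own last
move).  A pair of such strategies induces a Markov chain on the four
outcomes; the long-run average payoff of each player is the stationary (or,
for reducible chains, limiting time-average) distribution dotted with the
player's payoff vector.

State order is fixed as (CC, CD, DC, DD) from the focal player X's
perspective everywhere in this package.  The coplayer Y observes the
letter-swapped outcome, so Y's cooperation probability in X-state ``s`` is
``q[swap(s)]`` with CD and DC exchanged.

Two payoff routes are provided: the ``chain`` method (stationary solve,
always applicable, including reducible chains) and the ``determinant``
method (the Press–Dyson determinant ratio, valid when its denominator is
nonzero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .game_core import PayoffMatrix

__all__ = [
    "STATES",
    "MemoryOneStrategy",
    "StationaryDistribution",
    "PayoffPair",
    "as_strategy",
    "transition_matrix",
    "stationary_distribution",
    "limiting_distribution",
    "recurrent_classes",
    "average_payoffs",
    "payoff_derivative",
    "perturb_with_noise",
    "DeterminantSingularError",
]

#: outcome order from the focal player's perspective
STATES = ("CC", "CD", "DC", "DD")

#: index permutation mapping X-perspective states to Y-perspective states
_SWAP = np.array([0, 2, 1, 3])

#: support threshold for edges of the reachability graph (float inputs)
_SUPPORT_TOL = 1e-15

MemoryOneStrategy = np.ndarray  # shape (4,) vector of cooperation probabilities


class DeterminantSingularError(ZeroDivisionError):
    """Determinant payoff method applied where its denominator vanishes."""


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run weights over the outcomes (CC, CD, DC, DD) from X's perspective."""

    vCC: float
    vCD: float
    vDC: float
    vDD: float

    def as_array(self) -> np.ndarray:
        return np.array([self.vCC, self.vCD, self.vDC, self.vDD])

    @staticmethod
    def from_array(v: np.ndarray) -> "StationaryDistribution":
        v = np.asarray(v, dtype=float)
        return StationaryDistribution(*(float(x) for x in v))


@dataclass(frozen=True)
class PayoffPair:
    """Long-run average payoffs of the focal player (sX) and coplayer (sY)."""

    sX: float
    sY: float


def as_strategy(p: Sequence[float]) -> MemoryOneStrategy:
    """Validate and coerce a memory-one strategy to a float vector in [0,1]^4."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (4,):
        raise ValueError(f"memory-one strategy must have 4 entries, got shape {arr.shape}")
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError(f"strategy entries must lie in [0, 1], got {arr}")
    return np.clip(arr, 0.0, 1.0)


def transition_matrix(p: Sequence[float], q: Sequence[float]) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix of the outcome chain.

    Rows and columns are ordered (CC, CD, DC, DD) from X's perspective; the
    two players act independently, X cooperating with probability ``p[s]``
    and Y with probability ``q[swap(s)]``.
    """
    p = as_strategy(p)
    qx = as_strategy(q)[_SWAP]
    M = np.empty((4, 4))
    M[:, 0] = p * qx
    M[:, 1] = p * (1.0 - qx)
    M[:, 2] = (1.0 - p) * qx
    M[:, 3] = (1.0 - p) * (1.0 - qx)
    return M


def recurrent_classes(M: np.ndarray, support_tol: float = _SUPPORT_TOL) -> list[list[int]]:
    """Recurrent communicating classes of a finite row-stochastic matrix.

    A strongly connected component of the support graph (edge present iff
    transition probability exceeds ``support_tol``) is recurrent iff no edge
    leaves it.
    """
    n = M.shape[0]
    support = M > support_tol
    n_comp, labels = connected_components(csr_matrix(support), directed=True, connection="strong")
    classes: list[list[int]] = [[] for _ in range(n_comp)]
    for state, lab in enumerate(labels):
        classes[lab].append(state)
    out = []
    for members in classes:
        inside = np.zeros(n, dtype=bool)
        inside[members] = True
        if not support[np.ix_(members, ~inside)].any():
            out.append(sorted(members))
    return sorted(out)


def _stationary_irreducible(M_sub: np.ndarray) -> np.ndarray:
    """Unique stationary distribution of an irreducible chain (any period).

    Solves the left null-space system with the normalization constraint
    replacing one equation; deterministic dense solve.
    """
    k = M_sub.shape[0]
    if k == 1:
        return np.array([1.0])
    A = M_sub.T - np.eye(k)
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    v = np.linalg.solve(A, b)
    # one step of iterative refinement sharpens near-reducible cases
    r = b - (np.vstack([(M_sub.T - np.eye(k))[:-1], np.ones(k)]) @ v)
    try:
        v = v + np.linalg.solve(A, r)
    except np.linalg.LinAlgError:  # pragma: no cover - refinement is best-effort
        pass
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def limiting_distribution(
    M: np.ndarray,
    initial: Optional[Sequence[float]] = None,
    support_tol: float = _SUPPORT_TOL,
) -> np.ndarray:
    """Limiting time-average distribution of a finite chain from ``initial``.

    With a unique recurrent class the result is its stationary distribution
    regardless of the start.  With several, the chain's eventual class is
    random; the result mixes each class's internal stationary distribution
    with the absorption probabilities from ``initial`` (default: all mass on
    state 0).
    """
    n = M.shape[0]
    if initial is None:
        init = np.zeros(n)
        init[0] = 1.0
    else:
        init = np.asarray(initial, dtype=float)
        if init.shape != (n,) or np.any(init < 0) or not np.isclose(init.sum(), 1.0):
            raise ValueError("initial must be a probability distribution over the states")

    classes = recurrent_classes(M, support_tol)
    pis = [_stationary_irreducible(M[np.ix_(c, c)]) for c in classes]
    if len(classes) == 1:
        v = np.zeros(n)
        v[classes[0]] = pis[0]
        return v

    recurrent = sorted(s for c in classes for s in c)
    transient = [s for s in range(n) if s not in recurrent]
    weights = np.zeros(len(classes))
    for ci, c in enumerate(classes):
        weights[ci] += init[c].sum()
    if transient and init[transient].sum() > 0:
        Q = M[np.ix_(transient, transient)]
        Rmat = np.column_stack([M[np.ix_(transient, c)].sum(axis=1) for c in classes])
        absorb = np.linalg.solve(np.eye(len(transient)) - Q, Rmat)
        weights += init[transient] @ absorb
    v = np.zeros(n)
    for w, c, pi in zip(weights, classes, pis):
        v[c] += w * pi
    return v / v.sum()


def stationary_distribution(
    p: Sequence[float],
    q: Sequence[float],
    initial: Optional[Sequence[float]] = None,
) -> StationaryDistribution:
    """Long-run outcome distribution for the pair (p, q).

    For reducible chains the default initial condition puts all mass on
    mutual cooperation in round one (both players open by cooperating).
    """
    v = limiting_distribution(transition_matrix(p, q), initial=initial)
    return StationaryDistribution.from_array(v)


def _press_dyson_det(p: np.ndarray, qx: np.ndarray, f: np.ndarray) -> float:
    """The 4x4 determinant D(p, q, f) of the Press–Dyson construction.

    ``qx`` is the coplayer's cooperation probability already re-indexed to
    X-perspective states.
    """
    own_coop = np.array([1.0, 1.0, 0.0, 0.0])  # X cooperated last round in CC, CD
    other_coop = np.array([1.0, 0.0, 1.0, 0.0])  # Y cooperated last round in CC, DC
    D = np.column_stack([p * qx - own_coop * other_coop, p - own_coop, qx - other_coop, f])
    return float(np.linalg.det(D))


def average_payoffs(
    p: Sequence[float],
    q: Sequence[float],
    payoffs: PayoffMatrix,
    method: Literal["chain", "determinant"] = "chain",
    initial: Optional[Sequence[float]] = None,
) -> PayoffPair:
    """Long-run average payoffs (sX, sY) of the pair (p, q).

    ``method="chain"`` dots the limiting distribution with the payoff
    vectors and is always applicable.  ``method="determinant"`` uses the
    Press–Dyson determinant ratio and raises
    :class:`DeterminantSingularError` when its denominator (the determinant
    with the all-ones column) is numerically zero — e.g. for reducible
    chains such as TFT vs TFT.
    """
    fx = np.array(payoffs.focal_vector())
    fy = np.array(payoffs.coplayer_vector())
    if method == "chain":
        v = stationary_distribution(p, q, initial=initial).as_array()
        return PayoffPair(float(v @ fx), float(v @ fy))
    if method == "determinant":
        pa = as_strategy(p)
        qx = as_strategy(q)[_SWAP]
        denom = _press_dyson_det(pa, qx, np.ones(4))
        scale = max(1.0, abs(_press_dyson_det(pa, qx, fx)), abs(_press_dyson_det(pa, qx, fy)))
        if abs(denom) < 1e-12 * scale:
            raise DeterminantSingularError(
                "Press-Dyson denominator determinant is (near-)zero for this pair; "
                "use method='chain' instead"
            )
        return PayoffPair(
            _press_dyson_det(pa, qx, fx) / denom,
            _press_dyson_det(pa, qx, fy) / denom,
        )
    raise ValueError(f"unknown method {method!r}; expected 'chain' or 'determinant'")


def payoff_derivative(
    strategy_family: Callable[[float], Sequence[float]],
    q: Sequence[float],
    payoffs: PayoffMatrix,
    theta0: float,
    which: Literal["focal", "coplayer"] = "focal",
    h: Optional[float] = None,
    bounds: Optional[tuple[float, float]] = None,
) -> float:
    """Numeric derivative of a player's payoff along a parameterized family.

    ``strategy_family`` maps a scalar parameter to the focal player's
    memory-one strategy.  Central differences with adaptive step
    ``h = 1e-6 * max(1, |theta0|)`` by default; if ``theta0`` sits within
    ``h`` of a supplied admissible boundary, a one-sided difference is used
    and a warning is emitted.
    """
    if h is None:
        h = 1e-6 * max(1.0, abs(theta0))

    def s(theta: float) -> float:
        pair = average_payoffs(strategy_family(theta), q, payoffs)
        return pair.sX if which == "focal" else pair.sY

    lo, hi = bounds if bounds is not None else (-np.inf, np.inf)
    if theta0 - h < lo or theta0 + h > hi:
        warnings.warn(
            f"theta0={theta0} within step {h} of the admissible boundary; "
            "using a one-sided difference",
            stacklevel=2,
        )
        if theta0 - h < lo:
            return (s(theta0 + h) - s(theta0)) / h
        return (s(theta0) - s(theta0 - h)) / h
    return (s(theta0 + h) - s(theta0 - h)) / (2.0 * h)


def perturb_with_noise(strategy: Sequence[float], eps: float) -> MemoryOneStrategy:
    """Apply an implementation-error rate: each action flips with probability eps.

    Entrywise ``p -> (1-eps) p + eps (1-p)``; requires ``0 <= eps < 0.5``.
    """
    if not 0.0 <= eps < 0.5:
        raise ValueError(f"error rate must satisfy 0 <= eps < 0.5, got {eps}")
    p = as_strategy(strategy)
    return (1.0 - eps) * p + eps * (1.0 - p)
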