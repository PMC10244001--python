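"""Finite-population Moran dynamics in the rare-mutation limit.

Competition between two memory-one strategies A and B in a population of
size N is summarized by their 2x2 matrix of long-run pairwise IPD payoffs.
In a mixed state with i copies of A, each player's expected payoff averages
over the other N-1 individuals (self excluded); fitness is exponential in
payoff, ``f = exp(beta * payoff)``, with the linear map ``1 + beta *
payoff`` as an option.  The fixation probability of a single A mutant is
the standard birth-death absorption probability, accumulated in log domain
so strong selection cannot overflow.

Under rare mutations the population is monomorphic almost always, and
evolution reduces to a Markov chain over monomorphic states whose
transitions are fixation probabilities; its stationary distribution is the
long-run strategy abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .game_core import PayoffMatrix
from .markov_engine import as_strategy, average_payoffs, limiting_distribution

__all__ = [
    "MoranConfig",
    "AveragePayoffMatrix2x2",
    "pairwise_payoff_matrix",
    "favored_over",
    "minimal_favoring_N",
    "fixation_probability",
    "dominance_graph",
    "rare_mutation_abundance",
]

#: |rho - 1/N| below this counts as neutral evolution
_NEUTRAL_TOL = 1e-12


@dataclass(frozen=True)
class MoranConfig:
    """Population size N, selection strength beta, and fitness map."""

    N: int = 100
    beta: float = 0.1
    fitness_map: Literal["exponential", "linear"] = "exponential"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size must be >= 2, got {self.N}")
        if self.beta < 0:
            raise ValueError(f"selection strength must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class AveragePayoffMatrix2x2:
    """Long-run IPD payoffs of a row strategy vs a column strategy."""

    a11: float  # row vs row
    a12: float  # row vs column
    a21: float  # column vs row
    a22: float  # column vs column


def pairwise_payoff_matrix(
    A: Sequence[float], B: Sequence[float], payoffs: PayoffMatrix
) -> AveragePayoffMatrix2x2:
    """All four long-run pairwise payoffs between strategies A and B."""
    A, B = as_strategy(A), as_strategy(B)
    return AveragePayoffMatrix2x2(
        a11=average_payoffs(A, A, payoffs).sX,
        a12=average_payoffs(A, B, payoffs).sX,
        a21=average_payoffs(B, A, payoffs).sX,
        a22=average_payoffs(B, B, payoffs).sX,
    )


def favored_over(matrix: AveragePayoffMatrix2x2, N: int) -> bool:
    """Whether the row strategy is favored over the column strategy at size N.

    The strict low-mutation selection condition
    ``(N-2) a11 + N a12 > N a21 + (N-2) a22``, valid for any selection
    strength and mutation rate.
    """
    if N < 2:
        raise ValueError("population size must be >= 2")
    return (N - 2) * matrix.a11 + N * matrix.a12 > N * matrix.a21 + (N - 2) * matrix.a22


def minimal_favoring_N(matrix: AveragePayoffMatrix2x2) -> Optional[int]:
    """Smallest N >= 2 at which the row strategy is favored, or None.

    The condition is linear in N: ``N d > e`` with
    ``d = a11 + a12 - a21 - a22`` and ``e = 2 (a11 - a22)``.
    """
    d = matrix.a11 + matrix.a12 - matrix.a21 - matrix.a22
    e = 2.0 * (matrix.a11 - matrix.a22)
    if d > 0:
        n = int(np.floor(e / d)) + 1
        return max(2, n)
    # d <= 0: larger N never helps; only N = 2 can qualify
    return 2 if favored_over(matrix, 2) else None


def _log_fitness_ratio(pi_B: np.ndarray, pi_A: np.ndarray, config: MoranConfig) -> np.ndarray:
    """log(f_B / f_A) per mixed state under the configured fitness map."""
    if config.fitness_map == "exponential":
        return config.beta * (pi_B - pi_A)
    if config.fitness_map == "linear":
        fA = 1.0 + config.beta * pi_A
        fB = 1.0 + config.beta * pi_B
        if np.any(fA <= 0) or np.any(fB <= 0):
            raise ValueError("linear fitness map produced non-positive fitness; lower beta")
        return np.log(fB) - np.log(fA)
    raise ValueError(f"unknown fitness map {config.fitness_map!r}")


def fixation_probability(
    mutant: Sequence[float],
    resident: Sequence[float],
    payoffs: PayoffMatrix,
    config: MoranConfig,
) -> float:
    """Fixation probability of one mutant in a resident Moran population.

    With i mutants, the mutant payoff is
    ``[(i-1) pi_AA + (N-i) pi_AB] / (N-1)`` and the resident payoff
    ``[i pi_BA + (N-i-1) pi_BB] / (N-1)`` (self-excluded averaging); the
    absorption probability is ``1 / (1 + sum_k prod_{j<=k} gamma_j)`` with
    ``gamma_j = f_resident(j) / f_mutant(j)``.  Neutral drift (beta = 0, or
    identical strategies) returns exactly 1/N.
    """
    m = pairwise_payoff_matrix(mutant, resident, payoffs)
    N = config.N
    i = np.arange(1, N)  # mixed states with 1..N-1 mutants
    pi_A = ((i - 1) * m.a11 + (N - i) * m.a12) / (N - 1)
    pi_B = (i * m.a21 + (N - i - 1) * m.a22) / (N - 1)
    log_gamma = _log_fitness_ratio(pi_B, pi_A, config)
    cum = np.cumsum(log_gamma)
    if np.max(np.abs(cum)) < 500.0:
        return float(1.0 / (1.0 + np.sum(np.exp(cum))))
    log_denom = logsumexp(np.concatenate([[0.0], cum]))
    return float(np.exp(-log_denom))


def _fixation_matrix(
    strategies: Sequence[Sequence[float]], payoffs: PayoffMatrix, config: MoranConfig
) -> np.ndarray:
    """rho[i, j] = fixation probability of strategy i invading resident j."""
    K = len(strategies)
    rho = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            if i != j:
                rho[i, j] = fixation_probability(strategies[i], strategies[j], payoffs, config)
    return rho


def dominance_graph(
    strategies: Sequence[Sequence[float]],
    payoffs: PayoffMatrix,
    config: MoranConfig,
    labels: Optional[Sequence[str]] = None,
    neutral_tol: float = _NEUTRAL_TOL,
) -> nx.DiGraph:
    """Pairwise invasion-dominance graph of a strategy set.

    Edge A -> B (kind 'dominance') when B's invasion of A is favored
    (rho > 1/N) and A's invasion of B is disfavored (rho < 1/N); a pair
    with both fixation probabilities within ``neutral_tol`` of 1/N gets a
    symmetric pair of 'neutral' edges.
    """
    if len(strategies) < 2:
        raise ValueError("need at least two strategies")
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(len(strategies))]
    rho = _fixation_matrix(strategies, payoffs, config)
    inv_N = 1.0 / config.N
    G = nx.DiGraph()
    for lab, strat in zip(labels, strategies):
        G.add_node(lab, strategy=np.asarray(strat, dtype=float))
    K = len(strategies)
    for a in range(K):
        for b in range(a + 1, K):
            r_ba, r_ab = rho[b, a], rho[a, b]  # b invades a / a invades b
            if abs(r_ba - inv_N) < neutral_tol and abs(r_ab - inv_N) < neutral_tol:
                G.add_edge(labels[a], labels[b], kind="neutral", rho=r_ba)
                G.add_edge(labels[b], labels[a], kind="neutral", rho=r_ab)
            elif r_ba > inv_N and r_ab < inv_N:
                G.add_edge(labels[a], labels[b], kind="dominance", rho=r_ba)
            elif r_ab > inv_N and r_ba < inv_N:
                G.add_edge(labels[b], labels[a], kind="dominance", rho=r_ab)
    return G


def rare_mutation_abundance(
    strategies: Sequence[Sequence[float]],
    payoffs: PayoffMatrix,
    config: MoranConfig,
) -> np.ndarray:
    """Stationary abundance of each strategy in the rare-mutation limit.

    The embedded chain over monomorphic states moves from resident j to
    mutant i with probability ``rho[i, j] / (K - 1)``; the returned vector
    is its limiting distribution (uniform start if the chain is reducible)
    and sums to one.
    """
    K = len(strategies)
    if K < 2:
        raise ValueError("need at least two strategies")
    rho = _fixation_matrix(strategies, payoffs, config)
    M = rho.T / (K - 1)  # M[j, i] = transition resident j -> resident i
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return limiting_distribution(M, initial=np.full(K, 1.0 / K))
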