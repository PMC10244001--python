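"""Gradient-based adaptive learning dynamics against fixed or coadapting coplayers.

Three deterministic gradient flows are implemented, all built on exact
long-run payoffs of the two-player outcome chain (the gameplay chain is
assumed to equilibrate faster than learning, so no within-round simulation
is performed):

* reactive learning — a self-interested focal player using a reactive
  strategy ``[p1, p2, p1, p2]`` ascends its own payoff gradient on the
  unit square, against a fixed coplayer;
* extortion-factor learning — an extortionate ZD player whose payoff is
  independent of its normalization factor (guaranteed by an unbending
  coplayer) adapts its extortion factor ``chi`` by ``dchi/dt =
  tau * dsX/dchi``, clipped below at the fair limit ``chi = 1``;
* coadaptive dynamics — a reactive player and a class-A coplayer
  ``[1, q2, 0, q4]`` adapt simultaneously with relative timescale
  ``omega`` (omega = 0 freezes the coplayer, omega = 1 freezes the focal
  player).

Integration is explicit Euler with projection of the state onto its box;
gradient components pointing outward at a face are realized as zero motion
by the projection.  Gradients use central differences in the interior and
one-sided differences at the box boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .game_core import PayoffMatrix
from .markov_engine import as_strategy, average_payoffs
from .unbending import is_phi_independent
from .zd import ZDParams, phi_upper, zd_strategy

__all__ = [
    "LearningConfig",
    "Trajectory",
    "reactive_strategy",
    "reactive_gradient_field",
    "integrate_reactive_learning",
    "integrate_chi_learning",
    "integrate_coadaptive",
    "classify_attractor",
    "PhiDependenceError",
]


class PhiDependenceError(ValueError):
    """Raised when chi-learning is requested against a phi-dependent coplayer."""


@dataclass(frozen=True)
class LearningConfig:
    """Integration parameters for the gradient flows.

    dt: Euler step; steps: iteration cap; tol: convergence threshold on the
    per-step state change; tau: timescale of chi-learning; grad_h: finite
    difference step.
    """

    dt: float = 0.01
    steps: int = 200_000
    tol: float = 1e-10
    tau: float = 1.0
    grad_h: float = 1e-6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class Trajectory:
    """Time-indexed states, payoffs and terminal classification of a flow."""

    times: np.ndarray
    states: np.ndarray
    payoffs: np.ndarray  # columns (sX, sY)
    converged: bool
    classification: str = ""


def reactive_strategy(p1: float, p2: float) -> np.ndarray:
    """Reactive memory-one strategy [p1, p2, p1, p2]: respond only to the coplayer."""
    return as_strategy([p1, p2, p1, p2])


def _boxed_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, h: float
) -> np.ndarray:
    """Finite-difference gradient on the unit box, one-sided at the faces."""
    g = np.empty_like(x)
    for i in range(x.size):
        lo = x.copy()
        hi = x.copy()
        step = 2.0 * h
        if x[i] + h > 1.0:
            hi[i] = x[i]
            lo[i] = x[i] - h
            step = h
        elif x[i] - h < 0.0:
            hi[i] = x[i] + h
            lo[i] = x[i]
            step = h
        else:
            hi[i] = x[i] + h
            lo[i] = x[i] - h
        g[i] = (f(hi) - f(lo)) / step
    return g


def reactive_gradient_field(
    q: Sequence[float],
    payoffs: PayoffMatrix,
    p1_grid: Optional[Sequence[float]] = None,
    p2_grid: Optional[Sequence[float]] = None,
    grad_h: float = 1e-6,
):
    """Payoff gradient of a reactive focal player over a (p1, p2) grid.

    Returns (P1, P2, G1, G2, SX): meshgrid coordinates, the two gradient
    components of sX, and the payoff sX in situ.
    """
    q = as_strategy(q)
    p1_grid = np.linspace(0.0, 1.0, 11) if p1_grid is None else np.asarray(p1_grid, dtype=float)
    p2_grid = np.linspace(0.0, 1.0, 11) if p2_grid is None else np.asarray(p2_grid, dtype=float)
    P1, P2 = np.meshgrid(p1_grid, p2_grid, indexing="ij")
    G1 = np.empty_like(P1)
    G2 = np.empty_like(P1)
    SX = np.empty_like(P1)

    def sx(x: np.ndarray) -> float:
        return average_payoffs(reactive_strategy(x[0], x[1]), q, payoffs).sX

    for i in range(P1.shape[0]):
        for j in range(P1.shape[1]):
            x = np.array([P1[i, j], P2[i, j]])
            SX[i, j] = sx(x)
            G1[i, j], G2[i, j] = _boxed_gradient(sx, x, grad_h)
    return P1, P2, G1, G2, SX


def _euler_box_flow(
    x0: np.ndarray,
    velocity: Callable[[np.ndarray], np.ndarray],
    payoff_at: Callable[[np.ndarray], tuple[float, float]],
    config: LearningConfig,
) -> Trajectory:
    """Explicit Euler with projection onto [0, 1]^d, stopping on small steps."""
    x = np.clip(np.asarray(x0, dtype=float), 0.0, 1.0)
    times = [0.0]
    states = [x.copy()]
    pay = [payoff_at(x)]
    converged = False
    for k in range(1, config.steps + 1):
        x_new = np.clip(x + config.dt * velocity(x), 0.0, 1.0)
        delta = np.max(np.abs(x_new - x))
        x = x_new
        times.append(k * config.dt)
        states.append(x.copy())
        pay.append(payoff_at(x))
        if delta < config.tol:
            converged = True
            break
    return Trajectory(
        times=np.array(times),
        states=np.array(states),
        payoffs=np.array(pay),
        converged=converged,
    )


def integrate_reactive_learning(
    p0: Sequence[float],
    q: Sequence[float],
    payoffs: PayoffMatrix,
    config: Optional[LearningConfig] = None,
) -> Trajectory:
    """Gradient ascent of a reactive player's payoff against fixed ``q``.

    State is (p1, p2) on the unit square; the terminal point is classified
    by :func:`classify_attractor` (stored on the trajectory).
    """
    config = config or LearningConfig()
    q = as_strategy(q)

    def sx(x: np.ndarray) -> float:
        return average_payoffs(reactive_strategy(x[0], x[1]), q, payoffs).sX

    def vel(x: np.ndarray) -> np.ndarray:
        return _boxed_gradient(sx, x, config.grad_h)

    def pay(x: np.ndarray) -> tuple[float, float]:
        pair = average_payoffs(reactive_strategy(x[0], x[1]), q, payoffs)
        return pair.sX, pair.sY

    traj = _euler_box_flow(np.asarray(p0, dtype=float), vel, pay, config)
    traj.classification = classify_attractor(traj)
    return traj


def integrate_chi_learning(
    chi0: float,
    q: Sequence[float],
    payoffs: PayoffMatrix,
    config: Optional[LearningConfig] = None,
    O: Optional[float] = None,
) -> Trajectory:
    """Extortion-factor learning dchi/dt = tau * dsX/dchi against fixed ``q``.

    Requires the coplayer to neutralize the normalization factor (checked
    via :func:`zdgames.unbending.is_phi_independent`); otherwise the
    one-dimensional reduction is invalid and :class:`PhiDependenceError`
    is raised.  The probe's phi is held at half its upper bound, recomputed
    at each chi; chi is clipped below at the fair limit 1.
    """
    config = config or LearningConfig()
    q = as_strategy(q)
    O = float(payoffs.P) if O is None else O
    if chi0 < 1.0:
        raise ValueError(f"initial extortion factor must be >= 1, got {chi0}")
    ok, spread = is_phi_independent(q, payoffs, O=O)
    if not ok:
        raise PhiDependenceError(
            f"coplayer's payoff depends on phi (max spread {spread:.3g}); "
            "the one-dimensional chi-learning reduction requires dsX/dphi = 0"
        )

    def pair_at(chi: float):
        phi = phi_upper(O, chi, payoffs) / 2.0
        p = zd_strategy(ZDParams(O, chi, phi), payoffs)
        return average_payoffs(p, q, payoffs)

    def sx(chi: float) -> float:
        return pair_at(chi).sX

    h = config.grad_h
    chi = float(chi0)
    times = [0.0]
    states = [np.array([chi])]
    pay0 = pair_at(chi)
    pays = [(pay0.sX, pay0.sY)]
    converged = False
    for k in range(1, config.steps + 1):
        if chi - h < 1.0:
            grad = (sx(chi + h) - sx(chi)) / h
        else:
            grad = (sx(chi + h) - sx(chi - h)) / (2.0 * h)
        chi_new = max(1.0, chi + config.dt * config.tau * grad)
        delta = abs(chi_new - chi)
        chi = chi_new
        pair = pair_at(chi)
        times.append(k * config.dt)
        states.append(np.array([chi]))
        pays.append((pair.sX, pair.sY))
        if delta < config.tol:
            converged = True
            break
    traj = Trajectory(
        times=np.array(times),
        states=np.array(states),
        payoffs=np.array(pays),
        converged=converged,
    )
    traj.classification = "fair_limit" if abs(chi - 1.0) < 1e-3 else (
        "converged" if converged else "max_steps"
    )
    return traj


def integrate_coadaptive(
    p0: Sequence[float],
    q0: Sequence[float],
    omega: float,
    payoffs: PayoffMatrix,
    config: Optional[LearningConfig] = None,
) -> Trajectory:
    """Coadaptive flow of a reactive player (p1, p2) and a class-A coplayer (q2, q4).

    The coplayer keeps the class-A anchors q1 = 1, q3 = 0 and adapts its
    free coordinates on its own payoff gradient:

        dp/dt = (1 - omega) * grad_p sX,   dq/dt = omega * grad_q sY.

    omega = 0 reproduces :func:`integrate_reactive_learning` against the
    fixed q0 exactly; omega = 1 freezes the focal player.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    config = config or LearningConfig()
    x0 = np.concatenate([np.asarray(p0, dtype=float), np.asarray(q0, dtype=float)])
    if x0.shape != (4,):
        raise ValueError("p0 and q0 must each have two entries")

    def strategies(x: np.ndarray):
        return reactive_strategy(x[0], x[1]), as_strategy([1.0, x[2], 0.0, x[3]])

    def pay(x: np.ndarray) -> tuple[float, float]:
        p, q = strategies(x)
        pair = average_payoffs(p, q, payoffs)
        return pair.sX, pair.sY

    def vel(x: np.ndarray) -> np.ndarray:
        pq = x[2:]

        def sx_of_p(pp: np.ndarray) -> float:
            return average_payoffs(
                reactive_strategy(pp[0], pp[1]), [1.0, pq[0], 0.0, pq[1]], payoffs
            ).sX

        v = np.zeros(4)
        gp = _boxed_gradient(sx_of_p, x[:2], config.grad_h)
        v[:2] = (1.0 - omega) * gp
        if omega > 0.0:
            pp = x[:2]

            def sy_of_q(qq: np.ndarray) -> float:
                return average_payoffs(
                    reactive_strategy(pp[0], pp[1]), [1.0, qq[0], 0.0, qq[1]], payoffs
                ).sY

            v[2:] = omega * _boxed_gradient(sy_of_q, pq, config.grad_h)
        return v

    traj = _euler_box_flow(x0, vel, pay, config)
    traj.classification = classify_attractor(traj)
    return traj


def classify_attractor(trajectory: Trajectory, tol: float = 1e-3) -> str:
    """Label the terminal focal state (p1, p2) of a finished trajectory.

    Labels: 'ALLD_corner' (0, 0); 'TFT_point' (1, 0), taking precedence
    over 'cooperative_edge' (p1 = 1); 'interior' for a converged interior
    rest point; 'max_steps' when the flow neither converged nor reached a
    recognizable attractor.
    """
    p1, p2 = trajectory.states[-1][:2]
    if abs(p1) < tol and abs(p2) < tol:
        return "ALLD_corner"
    if abs(p1 - 1.0) < tol and abs(p2) < tol:
        return "TFT_point"
    if abs(p1 - 1.0) < tol:
        return "cooperative_edge"
    return "interior" if trajectory.converged else "max_steps"
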