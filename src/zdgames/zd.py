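"""Zero-determinant (ZD) strategy algebra.

A ZD strategy is the memory-one strategy

    p1 = 1 - phi (R - O)(chi - 1)
    p2 = 1 - phi [(T - O) chi + (O - S)]
    p3 = phi [(O - S) chi + (T - O)]
    p4 = phi (O - P)(chi - 1)

parameterized by the baseline payoff ``O`` in [P, R], the extortion factor
``chi >= 1`` and the normalization factor ``phi > 0``.  Against any
coplayer, its owner unilaterally enforces the linear payoff relation
``sX - O = chi (sY - O)``.  ``O = P`` gives the extortionate ZD family,
``O = R`` the generous one; ``chi = 1`` is admitted as the closed fairness
boundary (the TFT-like limit), and the ``chi -> infinity`` limit with
``phi' = phi * chi`` held fixed gives the equalizer strategies that pin the
coplayer's payoff at ``O``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .game_core import PayoffMatrix
from .markov_engine import MemoryOneStrategy, as_strategy, average_payoffs

__all__ = [
    "ZDParams",
    "AdmissibilityError",
    "zd_strategy",
    "phi_upper",
    "named_strategy",
    "NAMED_STRATEGIES",
    "verify_linear_relation",
    "extortion_vs_generous_payoff",
]


class AdmissibilityError(ValueError):
    """ZD parameters that do not yield a proper probability vector."""


@dataclass(frozen=True)
class ZDParams:
    """A ZD parameter triple (O, chi, phi) relative to some payoff matrix.

    ``O`` must lie in [P, R]; ``chi >= 1`` (chi = 1 is the fair/TFT limit);
    ``0 < phi <= phi_upper(O, chi, payoffs)``.
    """

    O: float
    chi: float
    phi: float

    def validate(self, payoffs: PayoffMatrix) -> None:
        R, S, T, P = payoffs.as_floats()
        if not P - 1e-12 <= self.O <= R + 1e-12:
            raise AdmissibilityError(f"baseline payoff O={self.O} outside [P, R] = [{P}, {R}]")
        if self.chi < 1.0:
            raise AdmissibilityError(f"extortion factor chi={self.chi} must be >= 1")
        ub = phi_upper(self.O, self.chi, payoffs)
        if not 0.0 < self.phi <= ub + 1e-12:
            raise AdmissibilityError(
                f"normalization factor phi={self.phi} outside the admissible interval (0, {ub}]"
            )


def _zd_coefficients(O: float, chi: float, payoffs: PayoffMatrix) -> np.ndarray:
    """Slopes of phi in the four entries of the ZD parameterization.

    p = [1, 1, 0, 0] + phi * [-c1, -c2, c3, c4] with all ci >= 0.
    """
    R, S, T, P = payoffs.as_floats()
    return np.array(
        [
            (R - O) * (chi - 1.0),
            (T - O) * chi + (O - S),
            (O - S) * chi + (T - O),
            (O - P) * (chi - 1.0),
        ]
    )


def phi_upper(O: float, chi: float, payoffs: PayoffMatrix) -> float:
    """Largest admissible normalization factor phi for given (O, chi).

    Each strategy entry is linear in phi with nonnegative slope, so the
    bound is the smallest reciprocal slope among the binding constraints.
    For the extortionate baseline O = P this reduces to the closed form
    ``1 / ((T-P) chi + (P-S))`` when ``T + S >= 2P`` and
    ``1 / ((P-S) chi + (T-P))`` otherwise.
    """
    coeff = _zd_coefficients(O, chi, payoffs)
    positive = coeff[coeff > 0]
    if positive.size == 0:
        # chi = 1 and O at both ends cannot happen (P < R); p2/p3 slopes are
        # always positive since T > O >= S is impossible to violate.
        raise AdmissibilityError("no binding constraint; parameters degenerate")
    return float(1.0 / positive.max())


def zd_strategy(params: ZDParams, payoffs: PayoffMatrix) -> MemoryOneStrategy:
    """Memory-one strategy vector of the ZD parameterization.

    Raises :class:`AdmissibilityError` (naming the violated component and
    the allowed phi interval) if any entry leaves [0, 1].
    """
    coeff = _zd_coefficients(params.O, params.chi, payoffs)
    base = np.array([1.0, 1.0, 0.0, 0.0])
    sign = np.array([-1.0, -1.0, 1.0, 1.0])
    p = base + sign * params.phi * coeff
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        bad = int(np.argmax(np.maximum(-p, p - 1.0)))
        ub = phi_upper(params.O, params.chi, payoffs)
        raise AdmissibilityError(
            f"ZD entry p{bad + 1}={p[bad]:.6g} outside [0, 1] for "
            f"(O={params.O}, chi={params.chi}, phi={params.phi}); "
            f"admissible phi interval is (0, {ub:.6g}]"
        )
    return np.clip(p, 0.0, 1.0)


def equalizer_strategy(O: float, phi_prime: float, payoffs: PayoffMatrix) -> MemoryOneStrategy:
    """Equalizer: the chi -> infinity ZD limit with phi' = phi * chi fixed.

    Pins the coplayer's payoff at ``O`` regardless of their strategy:
    ``p = [1 - phi'(R-O), 1 - phi'(T-O), phi'(O-S), phi'(O-P)]``.
    """
    R, S, T, P = payoffs.as_floats()
    if not P <= O <= R:
        raise AdmissibilityError(f"equalizer baseline O={O} outside [P, R] = [{P}, {R}]")
    p = np.array([1.0 - phi_prime * (R - O), 1.0 - phi_prime * (T - O),
                  phi_prime * (O - S), phi_prime * (O - P)])
    if phi_prime <= 0 or np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise AdmissibilityError(
            f"equalizer with O={O}, phi'={phi_prime} is not a probability vector: {p}"
        )
    return np.clip(p, 0.0, 1.0)


def _gtft(payoffs: PayoffMatrix) -> MemoryOneStrategy:
    """Generous tit-for-tat: forgive defection with the classical generosity level."""
    R, S, T, P = payoffs.as_floats()
    g = min(1.0 - (T - R) / (R - S), (R - P) / (T - P))
    if g < 0:
        raise AdmissibilityError("GTFT generosity is negative for this payoff matrix")
    return np.array([1.0, g, 1.0, g])


#: fixed named strategies (no parameters, no payoff dependence)
NAMED_STRATEGIES: dict[str, tuple[float, float, float, float]] = {
    "TFT": (1.0, 0.0, 1.0, 0.0),
    "WSLS": (1.0, 0.0, 0.0, 1.0),
    "ALLC": (1.0, 1.0, 1.0, 1.0),
    "ALLD": (0.0, 0.0, 0.0, 0.0),
    "PSO_GAMBLER": (1.0, 0.5217, 0.0, 0.1205),
    "WILLING": (1.0, 1.0, 1.0, 0.0),
}


def named_strategy(
    name: str,
    payoffs: Optional[PayoffMatrix] = None,
    chi: Optional[float] = None,
    phi: Optional[float] = None,
    O: Optional[float] = None,
    phi_prime: Optional[float] = None,
    delta: float = 0.0,
    eps: float = 0.0,
) -> MemoryOneStrategy:
    """Look up or construct a named memory-one strategy.

    Fixed vectors: TFT, WSLS, ALLC, ALLD, PSO_GAMBLER, WILLING.
    Parameterized: EXTORTIONATE(chi, phi), GENEROUS(chi, phi),
    EQUALIZER(O, phi_prime), GTFT, WILLING_UNBENDING(delta, eps) — these
    need ``payoffs`` (except WILLING_UNBENDING).
    """
    key = name.strip().upper()
    if key in NAMED_STRATEGIES:
        return np.array(NAMED_STRATEGIES[key])
    if key == "WILLING_UNBENDING":
        return as_strategy([1.0 - delta, 1.0 - delta, 1.0 - delta, eps])
    if payoffs is None:
        raise ValueError(f"strategy {name!r} requires a payoff matrix")
    if key == "GTFT":
        return _gtft(payoffs)
    if key == "EXTORTIONATE":
        if chi is None:
            raise ValueError("extortionate ZD requires chi")
        P = float(payoffs.P)
        phi = phi if phi is not None else phi_upper(P, chi, payoffs) / 2.0
        return zd_strategy(ZDParams(P, chi, phi), payoffs)
    if key == "GENEROUS":
        if chi is None:
            raise ValueError("generous ZD requires chi")
        R = float(payoffs.R)
        phi = phi if phi is not None else phi_upper(R, chi, payoffs) / 2.0
        return zd_strategy(ZDParams(R, chi, phi), payoffs)
    if key == "EQUALIZER":
        if O is None or phi_prime is None:
            raise ValueError("equalizer requires O and phi_prime")
        return equalizer_strategy(O, phi_prime, payoffs)
    raise ValueError(f"unknown strategy name {name!r}")


def verify_linear_relation(
    params: ZDParams, q: Sequence[float], payoffs: PayoffMatrix
) -> float:
    """Residual |sX - O - chi (sY - O)| of the enforced linear payoff relation."""
    p = zd_strategy(params, payoffs)
    pair = average_payoffs(p, q, payoffs)
    return abs(pair.sX - params.O - params.chi * (pair.sY - params.O))


def extortion_vs_generous_payoff(chi: float, chi2: float, payoffs: PayoffMatrix):
    """Closed-form payoffs of an extortioner (factor chi) vs a generous ZD (factor chi2).

    Both enforced linear relations hold simultaneously, so the payoff pair
    is their intersection, independent of either phi:

        sX = [P (chi - 1) + R chi (chi2 - 1)] / (chi chi2 - 1)

    with ``sY`` recovered from ``sX - P = chi (sY - P)``.  Strictly
    decreasing in chi for chi > 1, so extortion backfires: the extortioner
    would earn the full reward R only in the fair limit chi -> 1.
    """
    from .markov_engine import PayoffPair

    R, S, T, P = payoffs.as_floats()
    denom = chi * chi2 - 1.0
    if abs(denom) < 1e-14:
        raise ZeroDivisionError(
            "chi * chi2 = 1 is a singular limit (only possible at chi = chi2 = 1)"
        )
    sX = (P * (chi - 1.0) + R * chi * (chi2 - 1.0)) / denom
    sY = P + (sX - P) / chi if chi > 1.0 else sX
    return PayoffPair(sX, sY)
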