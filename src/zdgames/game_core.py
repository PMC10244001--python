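"""Stage-game definitions for the iterated prisoner's dilemma (IPD).

The one-shot prisoner's dilemma is specified by four payoffs: the reward
``R`` for mutual cooperation, the sucker's payoff ``S``, the temptation
``T``, and the punishment ``P`` for mutual defection, ordered
``T > R > P > S``.  Two derived structural facts matter throughout the
repeated game:

* the sign of ``T + S - 2P`` (the *regime*), which decides whether a pair
  alternating unilateral cooperation does better than mutual defection and
  flips the dominance properties of zero-determinant strategies; and
* whether ``2R > T + S`` holds, so that mutual cooperation beats
  alternating exploitation.

Payoffs supplied as integers or :class:`fractions.Fraction` are kept as
exact rationals so the regime test is exact; float inputs use a small sign
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from numbers import Rational
from typing import Union

__all__ = ["Regime", "PayoffMatrix", "make_payoffs", "donation_game", "GameValidationError"]

Number = Union[int, float, Fraction]

#: sign tolerance for the regime test when payoffs are floats
_FLOAT_SIGN_TOL = 1e-12


class GameValidationError(ValueError):
    """Raised when stage-game payoffs violate the prisoner's-dilemma ordering."""


class Regime(str, Enum):
    """Sign of ``T + S - 2P``."""

    ABOVE = "ABOVE"  # T + S > 2P (conventional IPD)
    BELOW = "BELOW"  # T + S < 2P (adversarial games)
    EQUAL = "EQUAL"  # degenerate boundary, admitted but treated explicitly downstream


@dataclass(frozen=True)
class PayoffMatrix:
    """The four stage-game payoffs with derived structural flags.

    Attributes
    ----------
    R, S, T, P:
        Stage payoffs satisfying ``T > R > P > S``.  Exact rationals when
        constructed from rational inputs, floats otherwise.
    """

    R: Number
    S: Number
    T: Number
    P: Number

    def __post_init__(self) -> None:
        pairs = [("T", self.T, "R", self.R), ("R", self.R, "P", self.P), ("P", self.P, "S", self.S)]
        for hi_name, hi, lo_name, lo in pairs:
            if not hi > lo:
                raise GameValidationError(
                    f"prisoner's dilemma ordering T > R > P > S violated: "
                    f"{hi_name}={hi} is not greater than {lo_name}={lo}"
                )

    @property
    def is_exact(self) -> bool:
        return all(isinstance(x, Rational) for x in (self.R, self.S, self.T, self.P))

    @property
    def regime(self) -> Regime:
        gap = self.T + self.S - 2 * self.P
        tol = 0 if self.is_exact else _FLOAT_SIGN_TOL
        if gap > tol:
            return Regime.ABOVE
        if gap < -tol:
            return Regime.BELOW
        return Regime.EQUAL

    @property
    def alternation_ok(self) -> bool:
        """True when mutual cooperation beats alternating exploitation (2R > T+S)."""
        return 2 * self.R > self.T + self.S

    def as_floats(self) -> tuple[float, float, float, float]:
        return (float(self.R), float(self.S), float(self.T), float(self.P))

    def focal_vector(self) -> tuple[float, float, float, float]:
        """Payoffs of the focal player over outcomes (CC, CD, DC, DD)."""
        return (float(self.R), float(self.S), float(self.T), float(self.P))

    def coplayer_vector(self) -> tuple[float, float, float, float]:
        """Payoffs of the coplayer over the same outcomes, seen from the focal side."""
        return (float(self.R), float(self.T), float(self.S), float(self.P))


def _coerce(x: Number) -> Number:
    """Keep rational inputs exact (ints become Fractions), floats stay floats."""
    if isinstance(x, Rational):
        return Fraction(x)
    return float(x)


def make_payoffs(R: Number, S: Number, T: Number, P: Number) -> PayoffMatrix:
    """Validate and build a :class:`PayoffMatrix`.

    Raises :class:`GameValidationError` naming the violated inequality when
    the ordering ``T > R > P > S`` fails.
    """
    return PayoffMatrix(_coerce(R), _coerce(S), _coerce(T), _coerce(P))


def donation_game(b: Number, c: Number) -> PayoffMatrix:
    """The donation game: cooperation pays ``b`` to the coplayer at cost ``c``.

    Payoffs are ``R = b - c``, ``S = -c``, ``T = b``, ``P = 0``; the game
    satisfies equal gains from switching (``T + S = R + P``) exactly.
    Requires ``b > c > 0``.
    """
    if not c > 0:
        raise GameValidationError(f"donation game requires cost c > 0, got c={c}")
    if not b > c:
        raise GameValidationError(f"donation game requires benefit b > cost c, got b={b}, c={c}")
    b, c = _coerce(b), _coerce(c)
    return make_payoffs(b - c, -c, b, 0)
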