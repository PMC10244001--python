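"""Classification and scanning of unbending strategies.

A fixed strategy ``q`` is *unbending* to extortion when, probed by the
extortionate ZD family (baseline ``O = P``, factor ``chi``, normalization
``phi``):

(i)  the extortioner's long-run payoff ``sX`` is independent of the hidden
     parameter ``phi`` (``dsX/dphi = 0``), and
(ii) ``sX`` is strictly decreasing in the extortion factor
     (``dsX/dchi < 0``),

so a payoff-maximizing extortioner is driven to the fair limit
``chi -> 1``.  Four structural families neutralize ``phi``:

    class A: q1 = 1 and q3 = 0          class B: q2 = q3 = 0 (only T+S < 2P)
    class C: q1 = q2 = q3               class D: q4 = hD(q1, q2, q3)

where ``hD`` is the same hyperplane satisfied by every ZD strategy; class D
contains all ZD strategies with baseline O > P.  Membership in the
unbending set itself is decided numerically by grid tests on the two
derivative conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game_core import PayoffMatrix, Regime
from .markov_engine import (
    PayoffPair,
    StationaryDistribution,
    as_strategy,
    average_payoffs,
)
from .zd import ZDParams, phi_upper, zd_strategy

__all__ = [
    "ClassMembership",
    "hD_value",
    "classify_structure",
    "is_phi_independent",
    "is_unbending",
    "scan_unbending_region",
    "wsls_stationary_vs_extortioner",
]

_DEFAULT_CHI_GRID = (1.5, 2.0, 4.0, 8.0)


@dataclass
class ClassMembership:
    """Structural class flags and the two numerical unbending tests."""

    in_A: bool = False
    in_B: bool = False
    in_C: bool = False
    in_D: bool = False
    phi_independent: bool = False
    chi_monotone_decreasing: bool = False
    details: dict = field(default_factory=dict)

    @property
    def is_unbending(self) -> bool:
        return self.phi_independent and self.chi_monotone_decreasing


def hD_value(q1: float, q2: float, q3: float, payoffs: PayoffMatrix) -> float:
    """Fourth coordinate of the class-D (ZD) hyperplane through (q1, q2, q3).

    ``hD = [T - R - P + S - (T+S-2P) q1 + (R-P)(q2+q3)] / (2R - T - S)``;
    undefined when ``2R = T + S``.
    """
    R, S, T, P = payoffs.as_floats()
    denom = 2.0 * R - T - S
    if abs(denom) < 1e-14:
        raise ZeroDivisionError("class-D hyperplane undefined when 2R = T + S")
    return (T - R - P + S - (T + S - 2.0 * P) * q1 + (R - P) * (q2 + q3)) / denom


def classify_structure(
    q: Sequence[float], payoffs: PayoffMatrix, tol: float = 1e-9
) -> ClassMembership:
    """Structural class flags (A-D) of ``q``, with equality tolerance ``tol``.

    Class B is forced false unless the payoff regime is BELOW (T+S < 2P),
    where it exists.
    """
    q1, q2, q3, q4 = (float(x) for x in as_strategy(q))
    m = ClassMembership()
    m.in_A = abs(q1 - 1.0) < tol and abs(q3) < tol
    m.in_B = abs(q2) < tol and abs(q3) < tol and payoffs.regime is Regime.BELOW
    m.in_C = abs(q1 - q2) < tol and abs(q2 - q3) < tol
    R, S, T = float(payoffs.R), float(payoffs.S), float(payoffs.T)
    if abs(2.0 * R - T - S) > 1e-14:
        m.in_D = abs(q4 - hD_value(q1, q2, q3, payoffs)) < tol
    return m


def _probe_payoff(
    q: np.ndarray, payoffs: PayoffMatrix, O: float, chi: float, phi: float
) -> PayoffPair:
    """Payoffs when the probing ZD player (O, chi, phi) faces fixed ``q``."""
    p = zd_strategy(ZDParams(O, chi, phi), payoffs)
    return average_payoffs(p, q, payoffs)


def is_phi_independent(
    q: Sequence[float],
    payoffs: PayoffMatrix,
    chi_grid: Sequence[float] = _DEFAULT_CHI_GRID,
    O: Optional[float] = None,
    n_phi: int = 9,
    tol: float = 1e-8,
) -> tuple[bool, float]:
    """Test whether the probing ZD player's payoff ignores phi against ``q``.

    For each chi in ``chi_grid``, evaluates sX on an ``n_phi``-point grid
    spanning (0, phi_upper]; returns (flag, max spread), true iff the
    spread stays below ``tol`` at every chi.
    """
    q = as_strategy(q)
    O = float(payoffs.P) if O is None else O
    worst = 0.0
    for chi in chi_grid:
        ub = phi_upper(O, chi, payoffs)
        if ub <= 0:
            raise ValueError(f"empty admissible phi interval at chi={chi}")
        phis = np.linspace(ub / n_phi, ub, n_phi)
        sx = [_probe_payoff(q, payoffs, O, chi, phi).sX for phi in phis]
        worst = max(worst, max(sx) - min(sx))
    return worst < tol, worst


def is_unbending(
    q: Sequence[float],
    payoffs: PayoffMatrix,
    O: Optional[float] = None,
    chi_range: tuple[float, float] = (1.0 + 1e-3, 10.0),
    n_grid: int = 64,
    tol: float = 1e-10,
    phi_tol: float = 1e-8,
    chi_grid: Sequence[float] = _DEFAULT_CHI_GRID,
) -> ClassMembership:
    """Full unbending test of ``q`` against the probing ZD family with baseline O.

    Combines the phi-independence test with a strict-decrease test of
    ``chi -> sX`` on an ``n_grid``-point grid over ``chi_range`` (every
    consecutive difference below ``-tol * step``); the probe's phi is fixed
    at half its upper bound, which is immaterial once phi-independence
    holds.  Failure of phi-independence short-circuits the monotonicity
    scan.  Boundary cases with a flat payoff profile (e.g. TFT, constant at
    P) are classified as not unbending.
    """
    q = as_strategy(q)
    O = float(payoffs.P) if O is None else O
    m = classify_structure(q, payoffs)
    m.phi_independent, spread = is_phi_independent(
        q, payoffs, chi_grid=chi_grid, O=O, tol=phi_tol
    )
    m.details["max_phi_spread"] = spread
    if not m.phi_independent:
        m.chi_monotone_decreasing = False
        return m

    chis = np.linspace(chi_range[0], chi_range[1], n_grid)
    step = chis[1] - chis[0]
    sx = np.array(
        [_probe_payoff(q, payoffs, O, chi, phi_upper(O, chi, payoffs) / 2.0).sX for chi in chis]
    )
    diffs = np.diff(sx)
    m.chi_monotone_decreasing = bool(np.all(diffs < -tol * step))
    m.details["max_chi_diff"] = float(diffs.max())
    m.details["chi_grid"] = chis
    m.details["sX_on_chi_grid"] = sx
    return m


def scan_unbending_region(
    class_form: str,
    payoffs: PayoffMatrix,
    probe_O: Optional[float] = None,
    resolution: int = 11,
    n_grid: int = 24,
    chi_grid: Sequence[float] = (1.5, 2.0, 4.0),
) -> pd.DataFrame:
    """Grid scan of the unbending region within a structural class.

    Class "A" scans the free coordinates (q2, q4) of [1, q2, 0, q4] over
    [0, 1]^2; class "D" scans (q1, q2, q3) with q4 = hD(q1, q2, q3),
    marking points where hD leaves [0, 1] as infeasible.  For class A in
    the BELOW regime (T + S < 2P) the scan also records where the fixed
    player strictly outperforms the probing extortioner (sY > sX at every
    chi of the monotonicity grid).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2 per axis")
    grid = np.linspace(0.0, 1.0, resolution)
    rows = []
    if class_form.upper() == "A":
        below = payoffs.regime is Regime.BELOW
        O = float(payoffs.P) if probe_O is None else probe_O
        for q2 in grid:
            for q4 in grid:
                q = np.array([1.0, q2, 0.0, q4])
                m = is_unbending(q, payoffs, O=O, n_grid=n_grid, chi_grid=chi_grid)
                outperforms = False
                if below and m.is_unbending:
                    pairs = [
                        _probe_payoff(q, payoffs, O, chi, phi_upper(O, chi, payoffs) / 2.0)
                        for chi in m.details["chi_grid"][:: max(1, n_grid // 8)]
                    ]
                    outperforms = all(pair.sY > pair.sX for pair in pairs)
                rows.append(
                    {"q2": q2, "q4": q4, "unbending": m.is_unbending, "outperforms": outperforms}
                )
        return pd.DataFrame(rows)
    if class_form.upper() == "D":
        O = float(payoffs.P) if probe_O is None else probe_O
        for q1 in grid:
            for q2 in grid:
                for q3 in grid:
                    q4 = hD_value(q1, q2, q3, payoffs)
                    feasible = 0.0 <= q4 <= 1.0
                    unb = False
                    if feasible:
                        q = np.array([q1, q2, q3, q4])
                        unb = is_unbending(
                            q, payoffs, O=O, n_grid=n_grid, chi_grid=chi_grid
                        ).is_unbending
                    rows.append(
                        {
                            "q1": q1,
                            "q2": q2,
                            "q3": q3,
                            "q4": q4,
                            "feasible": feasible,
                            "unbending": unb,
                        }
                    )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown class form {class_form!r}; expected 'A' or 'D'")


def wsls_stationary_vs_extortioner(
    chi: float, payoffs: PayoffMatrix
) -> tuple[StationaryDistribution, PayoffPair]:
    """Closed-form long-run outcome of extortionate ZD (factor chi) vs WSLS.

    Up to normalization the stationary weights are

        vCC = 0,  vCD = [T - P + chi (P - S)] / [chi (T - P) + P - S],
        vDC = 1,  vDD = 1,

    from the extortioner's perspective: mutual cooperation never recurs,
    and whether the extortioner cooperates unilaterally more often than
    WSLS (vCD > vDC) is decided exactly by the regime sign T + S - 2P —
    in the BELOW regime WSLS outperforms every extortioner.
    """
    if not chi > 1.0:
        raise ValueError(f"extortion factor must satisfy chi > 1, got {chi}")
    R, S, T, P = payoffs.as_floats()
    vCD = (T - P + chi * (P - S)) / (chi * (T - P) + P - S)
    raw = np.array([0.0, vCD, 1.0, 1.0])
    v = raw / raw.sum()
    fx = np.array(payoffs.focal_vector())
    fy = np.array(payoffs.coplayer_vector())
    return StationaryDistribution.from_array(v), PayoffPair(float(v @ fx), float(v @ fy))
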