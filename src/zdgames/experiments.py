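"""Monte-Carlo sweeps over random coplayers and ZD parameter grids.

Reproducible experiments behind the package's summary tables: scatter of
payoff pairs of a ZD player against coplayers drawn uniformly from
[0,1]^4, dominance probability as a function of the ZD baseline payoff,
payoff surfaces over the (phi, chi) control plane, and mutual-cooperation
degradation under implementation noise.  Every sweep records its seed,
grid and payoffs in the result metadata and is bit-reproducible from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game_core import PayoffMatrix
from .markov_engine import (
    as_strategy,
    average_payoffs,
    perturb_with_noise,
    stationary_distribution,
)
from .zd import ZDParams, phi_upper, zd_strategy

__all__ = [
    "SweepResult",
    "sample_random_strategies",
    "payoff_scatter",
    "dominance_probability",
    "payoff_surface",
    "noise_cooperation_curve",
]

#: payoff difference below which a match counts as a tie, not dominance
_TIE_TOL = 1e-12


@dataclass
class SweepResult:
    """A tidy table of sweep outputs plus the metadata to reproduce them."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def sample_random_strategies(n: int, seed: Optional[int] = None) -> np.ndarray:
    """n memory-one strategies i.i.d. uniform on [0, 1]^4, deterministic per seed."""
    if n < 1:
        raise ValueError(f"need at least one strategy, got n={n}")
    rng = np.random.default_rng(seed)
    return rng.random((n, 4))


def _uniform_phi(rng: np.random.Generator, upper: float) -> float:
    """Draw phi uniformly from the half-open admissible interval (0, upper]."""
    return upper * (1.0 - rng.random())


def payoff_scatter(
    O: float,
    chi: float,
    payoffs: PayoffMatrix,
    n: int = 2000,
    seed: Optional[int] = None,
) -> SweepResult:
    """Payoff pairs (sX, sY) of a ZD player against n random coplayers.

    For each coplayer the normalization factor is drawn uniformly from its
    admissible interval, so all points lie on the enforced line
    ``sX - O = chi (sY - O)``.
    """
    rng = np.random.default_rng(seed)
    qs = sample_random_strategies(n, seed=rng.integers(2**31))
    rows = []
    for q in qs:
        phi = _uniform_phi(rng, phi_upper(O, chi, payoffs))
        p = zd_strategy(ZDParams(O, chi, phi), payoffs)
        pair = average_payoffs(p, q, payoffs)
        rows.append({"sX": pair.sX, "sY": pair.sY, "phi": phi})
    return SweepResult(
        data=pd.DataFrame(rows),
        metadata={"O": O, "chi": chi, "payoffs": payoffs.as_floats(), "n": n, "seed": seed},
    )


def dominance_probability(
    O_grid: Sequence[float],
    chi: float,
    payoffs: PayoffMatrix,
    n: int = 2000,
    seed: Optional[int] = None,
) -> SweepResult:
    """Monte-Carlo P(sX > sY) of a ZD player per baseline payoff O.

    Ties (|sX - sY| below 1e-12) are counted as not dominant.  Each O gets
    its own fresh coplayer sample from the shared generator; the standard
    error of each estimate is included.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for O in O_grid:
        wins = 0
        for q in sample_random_strategies(n, seed=rng.integers(2**31)):
            phi = _uniform_phi(rng, phi_upper(O, chi, payoffs))
            p = zd_strategy(ZDParams(O, chi, phi), payoffs)
            pair = average_payoffs(p, q, payoffs)
            if pair.sX - pair.sY > _TIE_TOL:
                wins += 1
        prob = wins / n
        rows.append({"O": O, "p_dominant": prob, "se": np.sqrt(prob * (1 - prob) / n)})
    return SweepResult(
        data=pd.DataFrame(rows),
        metadata={"chi": chi, "payoffs": payoffs.as_floats(), "n": n, "seed": seed},
    )


def payoff_surface(
    chi_grid: Sequence[float],
    q: Sequence[float],
    payoffs: PayoffMatrix,
    O: Optional[float] = None,
    n_phi: int = 15,
    mono_tol: float = 1e-9,
) -> SweepResult:
    """The ZD player's payoff sX over the (phi, chi) control plane vs fixed q.

    Phi spans a fixed absolute grid up to the largest upper bound on the
    chi grid; points where phi exceeds phi_upper(chi) are inadmissible and
    never evaluated.  Metadata flags record whether every admissible
    per-chi slice is monotone (or constant) in phi, and whether any fixed-
    phi slice has an interior maximum in chi (the one-humped shape).
    """
    q = as_strategy(q)
    O = float(payoffs.P) if O is None else O
    uppers = {chi: phi_upper(O, chi, payoffs) for chi in chi_grid}
    ub_max = max(uppers.values())
    phis = np.linspace(ub_max / n_phi, ub_max, n_phi)
    sx = np.full((len(chi_grid), n_phi), np.nan)
    rows = []
    phi_monotone = True
    for ci, chi in enumerate(chi_grid):
        admissible = phis <= uppers[chi] + 1e-15
        for pj in np.nonzero(admissible)[0]:
            sx[ci, pj] = average_payoffs(
                zd_strategy(ZDParams(O, chi, phis[pj]), payoffs), q, payoffs
            ).sX
            rows.append({"chi": chi, "phi": phis[pj], "sX": sx[ci, pj]})
        slice_vals = sx[ci, admissible]
        d = np.diff(slice_vals)
        if d.size and not (np.all(d >= -mono_tol) or np.all(d <= mono_tol)):
            phi_monotone = False
    nonmono_chi = False
    for pj in range(n_phi):
        col = sx[:, pj]
        col = col[~np.isnan(col)]
        if col.size < 3:
            continue
        k = int(np.argmax(col))
        if 0 < k < col.size - 1 and col[k] > col[0] + mono_tol and col[k] > col[-1] + mono_tol:
            nonmono_chi = True
            break
    return SweepResult(
        data=pd.DataFrame(rows),
        metadata={
            "O": O,
            "payoffs": payoffs.as_floats(),
            "q": q.tolist(),
            "phi_monotone_per_chi": phi_monotone,
            "chi_nonmonotonic": nonmono_chi,
        },
    )


def noise_cooperation_curve(
    q: Sequence[float],
    payoffs: PayoffMatrix,
    eps_list: Sequence[float],
) -> SweepResult:
    """Mutual-cooperation weight vCC of noisy self-play at each error rate.

    Both copies of ``q`` pass through the implementation-error map before
    the long-run distribution is computed.
    """
    q = as_strategy(q)
    rows = []
    for eps in eps_list:
        noisy = perturb_with_noise(q, eps)
        v = stationary_distribution(noisy, noisy)
        rows.append({"eps": eps, "vCC": v.vCC})
    return SweepResult(
        data=pd.DataFrame(rows),
        metadata={"payoffs": payoffs.as_floats(), "q": q.tolist()},
    )
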