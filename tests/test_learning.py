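import numpy as np
import pytest

from zdgames import (
    LearningConfig,
    classify_attractor,
    integrate_chi_learning,
    integrate_coadaptive,
    integrate_reactive_learning,
    named_strategy,
    payoff_derivative,
    reactive_gradient_field,
    reactive_strategy,
)
from zdgames.learning import PhiDependenceError, Trajectory

FAST = LearningConfig(dt=0.05, steps=4000, tol=1e-9)

#: class-A coplayers in the donation game b=4, c=1 with qualitatively
#: different basins: the first has an attracting defection corner
#: (bistable), the second (the PSO Gambler) drives every start to full
#: cooperation p1 = 1
BISTABLE_A = [1.0, 0.2, 0.0, 0.1]
GLOBAL_A = [1.0, 0.5217, 0.0, 0.1205]


def test_gradient_neutral_on_cooperative_edge_vs_generous(donation):
    # against a generous ZD (class D, O=R) the payoff on the edge p1=1 is
    # flat in p2: once mutual cooperation locks in, forgiveness is free
    gen = named_strategy("GENEROUS", donation, chi=2.0)
    for p2 in (0.2, 0.5, 0.8):
        d = payoff_derivative(
            lambda t: reactive_strategy(1.0, t), gen, donation, p2, bounds=(0, 1)
        )
        assert d == pytest.approx(0.0, abs=1e-8)


def test_gradient_increasing_on_edge_vs_intermediate_zd(donation):
    from zdgames import ZDParams, phi_upper, zd_strategy

    O = 1.5  # strictly between P=0 and R=3
    inter = zd_strategy(ZDParams(O, 2.0, phi_upper(O, 2.0, donation) / 2), donation)
    for p2 in (0.2, 0.5, 0.8):
        d = payoff_derivative(
            lambda t: reactive_strategy(1.0, t), inter, donation, p2, bounds=(0, 1)
        )
        assert d > 1e-3


def test_gradient_vs_alld_pushes_cooperation_down(donation):
    # vs ALLD only the response-to-defection coordinate matters: sX falls
    # in p2 while p1 is payoff-neutral
    _, _, G1, G2, _ = reactive_gradient_field(
        named_strategy("ALLD"), donation, [0.2, 0.5, 0.8], [0.2, 0.5, 0.8]
    )
    assert np.all(G2 < 0)
    assert np.all(np.abs(G1) < 1e-8)


def test_alld_corner_is_fixed_vs_alld(donation):
    traj = integrate_reactive_learning([0.0, 0.0], named_strategy("ALLD"), donation, FAST)
    assert traj.classification == "ALLD_corner"
    assert np.allclose(traj.states[-1], [0, 0])


def test_extortionate_edge_learns_toward_tft(donation):
    # starts on the p2=0 edge (the extortionate ZD segment) against an
    # unbending class-A coplayer converge to TFT (1, 0)
    for p1 in (0.3, 0.6, 0.9):
        traj = integrate_reactive_learning([p1, 0.0], GLOBAL_A, donation, FAST)
        assert traj.classification == "TFT_point"


def test_bistability_vs_one_class_a_coplayer(donation):
    labels = set()
    for p1 in np.linspace(0.05, 0.95, 10):
        for p2 in np.linspace(0.05, 0.95, 10):
            traj = integrate_reactive_learning([p1, p2], BISTABLE_A, donation, FAST)
            labels.add(
                "full_coop" if traj.classification in ("cooperative_edge", "TFT_point")
                else traj.classification
            )
    assert "ALLD_corner" in labels and "full_coop" in labels


def test_global_convergence_vs_pso_gambler(donation):
    for p1 in np.linspace(0.05, 0.95, 6):
        for p2 in np.linspace(0.05, 0.95, 6):
            traj = integrate_reactive_learning([p1, p2], GLOBAL_A, donation, FAST)
            assert traj.classification in ("cooperative_edge", "TFT_point")


def test_golden_ratio_payoff_maximum_on_cooperative_edge(donation):
    # b/c = 4 exceeds (sqrt(5)+1)/2, so the payoff maximum against a
    # class-A unbending coplayer lies on the edge p1 = 1
    _, _, _, _, SX = reactive_gradient_field(
        GLOBAL_A, donation, np.linspace(0, 1, 9), np.linspace(0, 1, 9)
    )
    assert SX.max() == pytest.approx(SX[-1, :].max(), abs=1e-9)


def test_payoff_nondecreasing_along_learning_path(donation):
    traj = integrate_reactive_learning([0.4, 0.6], GLOBAL_A, donation, FAST)
    assert np.all(np.diff(traj.payoffs[:, 0]) > -1e-6)


def test_chi_learning_reaches_fair_limit(conventional):
    gen = named_strategy("GENEROUS", conventional, chi=2.0)
    traj = integrate_chi_learning(4.0, gen, conventional, LearningConfig(dt=0.05, steps=5000))
    assert traj.states[-1][0] == pytest.approx(1.0, abs=1e-6)
    # at the fair limit both players earn the full reward R
    assert traj.payoffs[-1][0] == pytest.approx(3.0, abs=1e-6)
    assert traj.classification == "fair_limit"


def test_chi_learning_strictly_decreasing_vs_pso(conventional, pso):
    traj = integrate_chi_learning(4.0, pso, conventional, LearningConfig(dt=0.05, steps=300))
    assert np.all(np.diff(traj.states[:, 0]) < 0)


def test_chi_learning_boundary_start_stays(conventional, pso):
    traj = integrate_chi_learning(1.0, pso, conventional, LearningConfig(dt=0.05, steps=50))
    assert traj.states[-1][0] == pytest.approx(1.0, abs=1e-9)


def test_chi_learning_rejects_phi_dependent_coplayer(conventional):
    with pytest.raises(PhiDependenceError):
        integrate_chi_learning(2.0, [0.4, 0.1, 0.9, 0.2], conventional)


def test_coadaptive_omega_zero_reduces_to_reactive(donation):
    cfg = LearningConfig(dt=0.05, steps=150)
    tc = integrate_coadaptive([0.5, 0.2], [0.5217, 0.1205], 0.0, donation, cfg)
    tr = integrate_reactive_learning([0.5, 0.2], GLOBAL_A, donation, cfg)
    n = min(len(tc.states), len(tr.states))
    assert np.max(np.abs(tc.states[:n, :2] - tr.states[:n])) < 1e-12
    assert np.max(np.abs(tc.states[:, 2:] - [0.5217, 0.1205])) == 0.0


def test_coadaptive_omega_one_freezes_focal_player(donation):
    cfg = LearningConfig(dt=0.05, steps=150)
    tc = integrate_coadaptive([0.5, 0.2], [0.5217, 0.1205], 1.0, donation, cfg)
    assert np.max(np.abs(tc.states[:, :2] - [0.5, 0.2])) == 0.0
    assert not np.allclose(tc.states[-1, 2:], [0.5217, 0.1205])


def test_coadaptive_intermediate_omega_reaches_fair_split(donation):
    cfg = LearningConfig(dt=0.05, steps=3000, tol=1e-9)
    tc = integrate_coadaptive([0.5, 0.2], [0.5217, 0.1205], 0.3, donation, cfg)
    sX, sY = tc.payoffs[-1]
    assert tc.states[-1][0] == pytest.approx(1.0, abs=1e-3)  # full cooperation by X
    assert sX == pytest.approx(sY, abs=1e-2)


def test_classify_attractor_labels():
    def traj_at(p1, p2, converged=True):
        s = np.array([[0.5, 0.5], [p1, p2]])
        return Trajectory(np.array([0, 1]), s, np.zeros((2, 2)), converged)

    assert classify_attractor(traj_at(1.0, 0.7)) == "cooperative_edge"
    assert classify_attractor(traj_at(0.0004, 0.0002)) == "ALLD_corner"
    # TFT takes precedence over the cooperative edge
    assert classify_attractor(traj_at(1.0, 0.0006)) == "TFT_point"
    assert classify_attractor(traj_at(0.5, 0.5, converged=True)) == "interior"
    assert classify_attractor(traj_at(0.5, 0.5, converged=False)) == "max_steps"
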