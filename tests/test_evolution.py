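import numpy as np
import pytest

from zdgames import (
    AveragePayoffMatrix2x2,
    MoranConfig,
    dominance_graph,
    favored_over,
    fixation_probability,
    minimal_favoring_N,
    named_strategy,
    pairwise_payoff_matrix,
    rare_mutation_abundance,
)


def brute_force_fixation(m: AveragePayoffMatrix2x2, N: int, beta: float) -> float:
    """Independent oracle: absorption probability of the full birth-death chain.

    Builds the (N+1)-state Moran transition matrix explicitly and solves
    the linear absorption system, rather than using the product formula.
    """
    T = np.zeros((N + 1, N + 1))
    for i in range(1, N):
        pi_A = ((i - 1) * m.a11 + (N - i) * m.a12) / (N - 1)
        pi_B = (i * m.a21 + (N - i - 1) * m.a22) / (N - 1)
        fA, fB = np.exp(beta * pi_A), np.exp(beta * pi_B)
        up = (i * fA / (i * fA + (N - i) * fB)) * (N - i) / N
        down = ((N - i) * fB / (i * fA + (N - i) * fB)) * i / N
        T[i, i + 1], T[i, i - 1] = up, down
        T[i, i] = 1.0 - up - down
    T[0, 0] = T[N, N] = 1.0
    Q = T[1:N, 1:N]
    R = T[1:N, [0, N]]
    absorb = np.linalg.solve(np.eye(N - 1) - Q, R)
    return absorb[0, 1]


@pytest.fixture(scope="module")
def pso_vs_ext(conventional=None):
    import zdgames

    g = zdgames.make_payoffs(3, 0, 5, 1)
    pso = named_strategy("PSO_GAMBLER")
    ext = named_strategy("EXTORTIONATE", g, chi=2.0)
    return g, pso, ext


def test_pairwise_matrix_worked_example(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    m = pairwise_payoff_matrix(pso, ext, g)
    # printed to one decimal: (R, 1.5, 2.0, P); the published Gambler
    # vector is itself truncated, hence the 0.05 tolerance
    assert m.a11 == pytest.approx(3.0, abs=1e-12)
    assert m.a22 == pytest.approx(1.0, abs=1e-12)
    assert m.a12 == pytest.approx(1.5, abs=0.05)
    assert m.a21 == pytest.approx(2.0, abs=0.05)
    # the extortioner enforces a21 - P = 2 (a12 - P) exactly
    assert m.a21 - 1 == pytest.approx(2 * (m.a12 - 1), abs=1e-10)


def test_pairwise_matrix_self_play_symmetry(conventional, wsls):
    m = pairwise_payoff_matrix(wsls, wsls, conventional)
    assert m.a11 == m.a12 == m.a21 == m.a22


def test_favored_over_condition():
    m = AveragePayoffMatrix2x2(3, 1.5, 2.0, 1)
    assert not favored_over(m, 2)
    assert favored_over(m, 100)
    # equality is never "favored"
    assert not favored_over(AveragePayoffMatrix2x2(2, 2, 2, 2), 50)


@pytest.mark.parametrize(
    "matrix, expected",
    [
        (AveragePayoffMatrix2x2(3, 1.5, 2.0, 1), 3),
        (AveragePayoffMatrix2x2(1, 0, 5, 1), None),
        (AveragePayoffMatrix2x2(2, 2, 1, 1), 2),
    ],
)
def test_minimal_favoring_N(matrix, expected):
    assert minimal_favoring_N(matrix) == expected


def test_minimal_favoring_N_agrees_with_direct_check():
    rng = np.random.default_rng(7)
    for _ in range(50):
        m = AveragePayoffMatrix2x2(*rng.uniform(0, 5, 4))
        n = minimal_favoring_N(m)
        if n is None:
            assert not any(favored_over(m, N) for N in range(2, 40))
        else:
            assert favored_over(m, n)
            assert not any(favored_over(m, N) for N in range(2, n))


def test_neutral_drift_is_exactly_one_over_N(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    for N in (2, 5, 100):
        assert fixation_probability(pso, ext, g, MoranConfig(N=N, beta=0.0)) == 1.0 / N
    # identical strategies are neutral at any selection strength
    assert fixation_probability(pso, pso, g, MoranConfig(N=50, beta=1.0)) == 1.0 / 50


def test_fixation_continuity_in_weak_selection(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    rho = fixation_probability(pso, ext, g, MoranConfig(N=40, beta=1e-8))
    assert rho == pytest.approx(1 / 40, abs=1e-6)


@pytest.mark.parametrize("N", [2, 3, 4, 5, 6])
@pytest.mark.parametrize("beta", [0.05, 0.7])
def test_product_formula_matches_absorption_oracle(pso_vs_ext, N, beta):
    g, pso, ext = pso_vs_ext
    m = pairwise_payoff_matrix(pso, ext, g)
    rho = fixation_probability(pso, ext, g, MoranConfig(N=N, beta=beta))
    assert rho == pytest.approx(brute_force_fixation(m, N, beta), abs=1e-12)


def test_strong_selection_large_N_no_overflow(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    rho = fixation_probability(ext, pso, g, MoranConfig(N=500, beta=5.0))
    assert 0.0 <= rho < 1e-6


def test_unbending_invades_extortioner_not_vice_versa(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    cfg = MoranConfig(N=100, beta=0.1)
    assert fixation_probability(pso, ext, g, cfg) > 1 / 100
    assert fixation_probability(ext, pso, g, cfg) < 1 / 100


def test_favorability_consistent_with_fixation_comparison(conventional, rng):
    # the linear condition agrees with comparing the two invasion
    # probabilities, at any selection strength
    cfg = MoranConfig(N=30, beta=0.05)
    for _ in range(25):
        A, B = rng.random(4), rng.random(4)
        m = pairwise_payoff_matrix(A, B, conventional)
        rho_A = fixation_probability(A, B, conventional, cfg)
        rho_B = fixation_probability(B, A, conventional, cfg)
        if abs(rho_A - rho_B) > 1e-12:
            assert favored_over(m, cfg.N) == (rho_A > rho_B)


def test_dominance_graph_arrows_out_of_extortioner(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    strategies = [pso, named_strategy("GENEROUS", g, chi=2.0), named_strategy("TFT"), ext]
    labels = ["PSO", "GZD", "TFT", "EZD"]
    G = dominance_graph(strategies, g, MoranConfig(N=100, beta=0.1), labels)
    for target in ("PSO", "GZD", "TFT"):
        assert G.has_edge("EZD", target)
        assert G.edges["EZD", target]["kind"] == "dominance"
    # the three unbending strategies mutually cooperate: neutral pairs
    assert G.edges["PSO", "GZD"]["kind"] == "neutral"


def test_dominance_graph_neutral_cases(conventional, tft):
    G = dominance_graph([tft, tft], conventional, MoranConfig(N=50, beta=0.5), ["a", "b"])
    assert G.edges["a", "b"]["kind"] == "neutral"
    G = dominance_graph(
        [named_strategy("WSLS"), tft], conventional, MoranConfig(N=50, beta=0.0), ["w", "t"]
    )
    assert G.edges["w", "t"]["kind"] == "neutral"


def test_abundance_uniform_under_neutrality(conventional, wsls, tft, pso):
    ab = rare_mutation_abundance([wsls, tft, pso], conventional, MoranConfig(N=60, beta=0.0))
    assert np.allclose(ab, 1 / 3, atol=1e-12)


def test_abundance_permutation_equivariant(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    gen = named_strategy("GENEROUS", g, chi=2.0)
    cfg = MoranConfig(N=100, beta=0.1)
    ab = rare_mutation_abundance([pso, gen, ext], g, cfg)
    ab_perm = rare_mutation_abundance([ext, pso, gen], g, cfg)
    assert np.allclose(ab, ab_perm[[1, 2, 0]], atol=1e-12)
    assert ab.sum() == pytest.approx(1.0, abs=1e-12)


def test_extortioner_abundance_vanishes_under_strong_selection(pso_vs_ext):
    g, pso, ext = pso_vs_ext
    strategies = [pso, named_strategy("GENEROUS", g, chi=2.0), named_strategy("TFT"), ext]
    ab = rare_mutation_abundance(strategies, g, MoranConfig(N=100, beta=1.0))
    assert ab[3] < 0.01
    assert np.all(ab[:3] > 1 / 4)
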