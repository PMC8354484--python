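"""Hill systems: right-hand sides, Newton, continuation, Monte-Carlo."""

import numpy as np
import pytest

from switchgrade import (
    build_hill_system,
    continue_curve,
    find_equilibrium,
    hysteretic_parameter_point,
    make_fixture,
    monte_carlo_hysteresis_score,
    parse_network,
)
from switchgrade.fixtures import benchmark_hill_parameters


@pytest.fixture(scope="module")
def bench_system():
    net = make_fixture("network12").network
    return build_hill_system(net, benchmark_hill_parameters(), 4)


class TestRightHandSide:
    def test_half_maximum_identity(self):
        net = parse_network("x0:(x1)\nx1:(x0)")
        p = {("g", 0): 1.0, ("g", 1): 1.0,
             ("l", 0, 1): 0.5, ("d", 0, 1): 2.0, ("t", 0, 1): 1.3,
             ("l", 1, 0): 0.5, ("d", 1, 0): 2.0, ("t", 1, 0): 0.7}
        system = build_hill_system(net, p, 7)
        H, _ = system.production(np.array([0.5, 1.3]))
        assert H[0] == pytest.approx(0.5 + 2.0 / 2)  # x1 sits at its threshold

    def test_large_exponent_approaches_switch(self, bench_system):
        net = bench_system.net
        stiff = build_hill_system(net, bench_system.params, 400)
        H, _ = stiff.production(np.array([0.1, 0.1, 0.1]))
        # far below every threshold: production at the summed low rates
        p = stiff.params
        assert H[2] == pytest.approx(p[("l", 2, 0)], rel=1e-6)

    @pytest.mark.parametrize("text, seed", [
        ("x0:(x0+x1+x2)\nx1:(x0+x2)\nx2:(x0)", 0),
        ("x0:(x1)(~x2)\nx1:(x0)\nx2:(x0)", 1),
        ("x0:(~x1)\nx1:(~x0)", 2),
    ])
    def test_jacobian_matches_finite_differences(self, text, seed):
        net = parse_network(text)
        rng = np.random.default_rng(seed)
        params = {("g", i): 1.0 for i in range(net.n_nodes)}
        for i in range(net.n_nodes):
            for src, _ in net.in_edges(i):
                params[("l", i, src)] = rng.uniform(0.2, 1.0)
                params[("d", i, src)] = rng.uniform(0.2, 2.0)
                params[("t", i, src)] = rng.uniform(0.3, 2.0)
            if not net.in_edges(i):
                params[("b", i)] = rng.uniform(0.2, 1.0)
        system = build_hill_system(net, params, 5)
        x = rng.uniform(0.3, 2.0, size=net.n_nodes)
        J = system.jac(x, 0.1)
        Jfd = np.zeros_like(J)
        for j in range(net.n_nodes):
            e = np.zeros(net.n_nodes)
            e[j] = 1e-6
            Jfd[:, j] = (system.rhs(x + e, 0.1) - system.rhs(x - e, 0.1)) / 2e-6
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-5


class TestEquilibria:
    def test_linear_system_equilibrium(self):
        net = parse_network("x0 :\nx1 : (x0)")
        p = {("g", 0): 1.0, ("g", 1): 1.0, ("b", 0): 0.8,
             ("l", 1, 0): 0.3, ("d", 1, 0): 1.0, ("t", 1, 0): 0.5}
        system = build_hill_system(net, p, 4)
        for guess in ([0.1, 0.1], [5.0, 5.0]):
            eq = find_equilibrium(system, guess)
            assert eq is not None
            assert eq[0] == pytest.approx(0.8, abs=1e-8)

    def test_positive_guess_required(self, bench_system):
        with pytest.raises(ValueError):
            find_equilibrium(bench_system, [0.0, 1.0, 1.0])

    def test_benchmark_low_equilibrium(self, bench_system):
        eq = find_equilibrium(bench_system, [0.3, 0.5, 0.1], s=0.0)
        assert eq is not None
        assert eq[2] < bench_system.params[("t", 0, 2)]


class TestContinuation:
    def test_monotone_system_has_no_folds(self):
        net = parse_network("x0 :\nx1 : (x0)")
        p = {("g", 0): 1.0, ("g", 1): 1.0, ("b", 0): 0.8,
             ("l", 1, 0): 0.3, ("d", 1, 0): 1.0, ("t", 1, 0): 0.5}
        system = build_hill_system(net, p, 4)
        eq = find_equilibrium(system, [0.8, 0.6])
        curve = continue_curve(system, eq, (0.0, 4.0))
        assert curve.complete and not curve.folds

    def test_benchmark_curve_two_folds(self, bench_system):
        eq = find_equilibrium(bench_system, [0.3, 0.5, 0.1], s=0.0)
        curve = continue_curve(bench_system, eq, (0.0, 4.0))
        assert curve.complete
        assert len(curve.folds) == 2
        for fold in curve.folds:
            assert fold.x_after[2] > fold.x_before[2]

    def test_equilibrium_residual_along_curve(self, bench_system):
        eq = find_equilibrium(bench_system, [0.3, 0.5, 0.1], s=0.0)
        curve = continue_curve(bench_system, eq, (0.0, 4.0))
        for s, x, _sign in curve.points[:: max(1, len(curve.points) // 20)]:
            assert np.linalg.norm(bench_system.rhs(x, s)) < 1e-7


class TestHystereticPoint:
    def test_benchmark_point_is_hysteretic(self, bench_system):
        assert hysteretic_parameter_point(bench_system, seed=3)

    def test_descending_fails_on_all_activator(self, bench_system):
        assert not hysteretic_parameter_point(
            bench_system, mode="descending", seed=3
        )

    def test_tiny_delta_cannot_switch(self):
        net = make_fixture("network12").network
        p = dict(benchmark_hill_parameters())
        for k in list(p):
            if k[0] == "d":
                p[k] = 1e-4
        system = build_hill_system(net, p, 4)
        assert not hysteretic_parameter_point(system, seed=3)


class TestMonteCarlo:
    def test_zero_samples_undefined(self, pg12, net12):
        score, recs = monte_carlo_hysteresis_score(
            net12, pg12, [(0, 1, 2)], 0, 30, seed=1
        )
        assert score is None and recs == []

    def test_deterministic_records(self, pg12, net12):
        f = pg12.factors
        verts = [(f[0].minimal_vertex(), f[1].essential_indices()[0],
                  f[2].essential_indices()[0])]
        a = monte_carlo_hysteresis_score(net12, pg12, verts, 6, 30, seed=9)
        b = monte_carlo_hysteresis_score(net12, pg12, verts, 6, 30, seed=9)
        assert a == b
        assert len(a[1]) == 6
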