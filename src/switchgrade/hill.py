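"""Hill-function ODE models and pseudo-arclength continuation validation.

The switching model's step nonlinearities are smoothed by Hill functions:
``H+ = ℓ + δ·x^n/(θ^n + x^n)`` (activation) and
``H- = ℓ + δ·θ^n/(θ^n + x^n)`` (repression), assembled per node with the
same sum-then-multiply algebra as the combinatorial model, plus an additive
input signal ``s`` on the input node:

    dx_i/dt = -γ_i x_i + H_i(x) + s·e_input

Equilibrium curves in ``s`` are traced by pseudo-arclength continuation;
saddle-node (fold) bifurcations are detected by sign changes of the
Jacobian determinant and refined by bisection.  A sampled parameter point
is declared *hysteretic* when, from random low-output initial guesses, some
equilibrium at s=0 continues to the end of the signal range through an even
number (at least two) of folds, the output coordinate stepping in the
expected direction across each fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import RegulatoryNetwork

__all__ = [
    "HillSystem",
    "ContinuationCurve",
    "build_hill_system",
    "find_equilibrium",
    "continue_curve",
    "hysteretic_parameter_point",
    "monte_carlo_hysteresis_score",
]


def _hill_terms(x, theta, n):
    """(increasing Hill ratio h, dh/dx), overflow-safe for large n."""
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        r = (theta / x) ** n
        if not np.isfinite(r):
            return 0.0, 0.0
        h = 1.0 / (1.0 + r)
        dh = n * r / (x * (1.0 + r) ** 2) if r > 0 else 0.0
    if not np.isfinite(dh):
        dh = 0.0
    return h, dh


@dataclass
class HillSystem:
    """Evaluable Hill ODE right-hand side with analytic Jacobian."""

    net: RegulatoryNetwork
    params: dict
    hill_n: float

    def __post_init__(self):
        if any(v <= 0 for v in self.params.values()):
            raise ValueError("Hill-system parameters must be positive")
        self._edges = [self.net.in_edges(i) for i in range(self.net.n_nodes)]
        self._gamma = np.array(
            [self.params[("g", i)] for i in range(self.net.n_nodes)]
        )

    @property
    def n(self) -> int:
        return self.net.n_nodes

    def production(self, x):
        """Λ-like smooth production vector H(x) and its Jacobian dH/dx."""
        N = self.n
        H = np.zeros(N)
        J = np.zeros((N, N))
        p = self.params
        for i in range(N):
            edges = self._edges[i]
            if not edges:
                H[i] = p[("b", i)]
                continue
            ssum = 0.0
            dsum = np.zeros(N)
            have_act = False
            prod = 1.0
            dprod = np.zeros(N)
            for src, sign in edges:
                l = p[("l", i, src)]
                d = p[("d", i, src)]
                th = p[("t", i, src)]
                h, dh = _hill_terms(x[src], th, self.hill_n)
                if sign > 0:
                    have_act = True
                    ssum += l + d * h
                    dsum[src] += d * dh
                else:
                    val = l + d * (1.0 - h)
                    dval = -d * dh
                    dprod = dprod * val
                    dprod[src] += prod * dval
                    prod *= val
            if have_act:
                H[i] = ssum * prod
                J[i, :] = dsum * prod + ssum * dprod
            else:
                H[i] = prod
                J[i, :] = dprod
        return H, J

    def rhs(self, x, s=0.0):
        H, _ = self.production(x)
        f = -self._gamma * x + H
        f[self.net.input_node] += s
        return f

    def jac(self, x, s=0.0):
        _, J = self.production(x)
        return J - np.diag(self._gamma)

    def out_thresholds(self, node: int) -> list[float]:
        """All thresholds read from ``x_node`` (empty for no-out nodes)."""
        return [
            self.params[("t", tgt, node)]
            for tgt in self.net.out_edges(node)
        ]


def build_hill_system(net: RegulatoryNetwork, params: dict, hill_n: float) -> HillSystem:
    """Assemble a Hill system; ``params`` uses the package-wide keys
    (γ as ``("g",i)``, per-edge ``("l",i,src)``, ``("d",i,src)``,
    ``("t",i,src)``, basal ``("b",i)``)."""
    return HillSystem(net=net, params=dict(params), hill_n=hill_n)


def find_equilibrium(system: HillSystem, guess, s=0.0,
                     tol=1e-10, max_iter=100):
    """Damped Newton from a strictly positive guess; None on failure."""
    x = np.asarray(guess, dtype=float).copy()
    if np.any(x <= 0):
        raise ValueError("initial guess must be strictly positive")
    for _ in range(max_iter):
        f = system.rhs(x, s)
        if np.linalg.norm(f) < tol:
            return x
        J = system.jac(x, s)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        base = np.linalg.norm(f)
        for _ in range(30):
            xn = x + lam * step
            if np.all(xn > 0) and np.linalg.norm(system.rhs(xn, s)) < base:
                break
            lam *= 0.5
        else:
            return None
        x = xn
    return x if np.linalg.norm(system.rhs(x, s)) < tol * 100 else None


@dataclass
class Fold:
    s: float
    x_before: np.ndarray
    x_after: np.ndarray


@dataclass
class ContinuationCurve:
    points: list          # (s, x, sign(det J))
    folds: list[Fold]
    complete: bool        # reached the end of the signal range
    hysteretic: bool = False


def _corrector(system, y, tangent, y_pred, tol=1e-10, max_iter=25):
    """Newton on [F(x,s); tangent·(y - y_pred)] = 0."""
    N = system.n
    y = y.copy()
    for _ in range(max_iter):
        x, s = y[:N], y[N]
        f = system.rhs(x, s)
        g = tangent @ (y - y_pred)
        res = np.concatenate([f, [g]])
        if np.linalg.norm(res) < tol:
            return y
        J = np.zeros((N + 1, N + 1))
        J[:N, :N] = system.jac(x, s)
        J[:N, N] = 0.0
        J[system.net.input_node, N] = 1.0
        J[N, :] = tangent
        try:
            step = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            return None
        y = y + step
        if np.any(y[:N] <= 0):
            return None
    return None


def _tangent(system, y, previous=None):
    N = system.n
    x, s = y[:N], y[N]
    A = np.zeros((N, N + 1))
    A[:, :N] = system.jac(x, s)
    A[system.net.input_node, N] = 1.0
    # nullspace of the bordered Jacobian
    _, _, vh = np.linalg.svd(A)
    t = vh[-1]
    if previous is not None and t @ previous < 0:
        t = -t
    elif previous is None and t[N] < 0:
        t = -t  # start moving toward increasing s
    return t / np.linalg.norm(t)


def continue_curve(
    system: HillSystem,
    start_x,
    s_range=(0.0, 4.0),
    initial_step=0.01,
    min_step=1e-5,
    max_step=0.1,
    max_steps=100_000,
    fold_tol=1e-8,
):
    """Pseudo-arclength predictor-corrector from an equilibrium at s_range[0].

    Tracks the sign of det(J) to locate folds, refines each fold location by
    bisection in arclength, and records the output-node value just before
    and just after each fold (from the accepted points flanking it).
    """
    s_lo, s_hi = s_range
    x0 = find_equilibrium(system, start_x, s=s_lo)
    if x0 is None:
        return ContinuationCurve([], [], complete=False)
    N = system.n
    y = np.concatenate([x0, [s_lo]])

    def detsign(yv):
        return float(np.sign(np.linalg.det(system.jac(yv[:N], yv[N]))))

    points = [(float(y[N]), y[:N].copy(), detsign(y))]
    folds = []
    t = _tangent(system, y)
    h = initial_step
    for _ in range(max_steps):
        y_pred = y + h * t
        y_new = _corrector(system, y_pred, t, y_pred)
        if y_new is None:
            h *= 0.5
            if h < min_step:
                return ContinuationCurve(points, folds, complete=False)
            continue
        sign_old = points[-1][2]
        sign_new = detsign(y_new)
        if sign_new != 0 and sign_old != 0 and sign_new != sign_old:
            fold = _refine_fold(system, y, y_new, t, fold_tol)
            folds.append(
                Fold(s=fold, x_before=points[-1][1].copy(),
                     x_after=y_new[:N].copy())
            )
        points.append((float(y_new[N]), y_new[:N].copy(), sign_new))
        t = _tangent(system, y_new, previous=t)
        y = y_new
        h = min(h * 1.3, max_step)
        if y[N] > s_hi:
            return ContinuationCurve(points, folds, complete=True)
        if y[N] < s_lo - 1.0 or np.any(y[:N] > 1e6):
            return ContinuationCurve(points, folds, complete=False)
    return ContinuationCurve(points, folds, complete=False)


def _refine_fold(system, y_a, y_b, tangent, tol):
    """Bisection on the determinant sign along the secant between points."""
    N = system.n

    def det_at(y):
        return float(np.linalg.det(system.jac(y[:N], y[N])))

    da = det_at(y_a)
    a, b = y_a.copy(), y_b.copy()
    for _ in range(60):
        if abs(b[N] - a[N]) < tol and np.linalg.norm(b[:N] - a[:N]) < 1e-6:
            break
        mid_pred = 0.5 * (a + b)
        mid = _corrector(system, mid_pred, tangent, mid_pred)
        if mid is None:
            break
        dm = det_at(mid)
        if (dm > 0) == (da > 0):
            a, da = mid, dm
        else:
            b = mid
    return float(0.5 * (a[N] + b[N]))


def hysteretic_parameter_point(
    system: HillSystem,
    mode: str = "ascending",
    guesses: int = 10,
    seed: int = 0,
    s_max: float = 4.0,
    **continuation_kw,
) -> bool:
    """The sampled-point hysteresis test.

    Random initial guesses are drawn in the low box ``0 < x_i ≤ min θ_{*,i}``
    (for descending mode the output coordinate is drawn in
    ``(max θ, 2·max θ]``); Newton at s=0 must land in the corresponding
    output band; successful equilibria are continued to ``s_max``; the point
    is hysteretic if some curve completes with an even number (≥ 2) of folds,
    the output value stepping up (ascending) or down (descending) across
    every fold.
    """
    net = system.net
    rng = np.random.default_rng(seed)
    out_node = net.output_node
    his = []
    for i in range(net.n_nodes):
        ths = system.out_thresholds(i)
        his.append(min(ths) if ths else 1.0)
    out_ths = system.out_thresholds(out_node)
    out_max = max(out_ths) if out_ths else 1.0

    seen: list[np.ndarray] = []
    for _ in range(guesses):
        guess = np.array([rng.uniform(0, hi) for hi in his])
        guess = np.maximum(guess, 1e-9)
        if mode == "descending":
            guess[out_node] = rng.uniform(out_max, 2 * out_max)
        eq = find_equilibrium(system, guess, s=0.0)
        if eq is None:
            continue
        x2 = eq[out_node]
        if mode == "ascending":
            if not (0 < x2 <= min(out_ths) if out_ths else x2 > 0):
                continue
        else:
            if not x2 > out_max:
                continue
        if any(np.linalg.norm(eq - e) < 1e-8 for e in seen):
            continue
        seen.append(eq)
        curve = continue_curve(system, eq, s_range=(0.0, s_max),
                               **continuation_kw)
        if not curve.complete or len(curve.folds) < 2 or len(curve.folds) % 2:
            continue
        ok = True
        for fold in curve.folds:
            before = fold.x_before[out_node]
            after = fold.x_after[out_node]
            if mode == "ascending" and not after > before:
                ok = False
            if mode == "descending" and not after < before:
                ok = False
        if ok:
            return True
    return False


def monte_carlo_hysteresis_score(
    net: RegulatoryNetwork,
    pg,
    parameter_vertices,
    n_samples: int,
    hill_n: float,
    seed: int = 0,
    mode: str = "ascending",
    guesses: int = 10,
    s_max: float = 4.0,
    **continuation_kw,
):
    """Fraction (percent) of sampled parameter points that are hysteretic.

    Samples are drawn by cycling over ``parameter_vertices`` (parameter-graph
    coordinate tuples) through the region sampler; per-sample outcomes are
    returned for audit.  Deterministic under a fixed seed.
    """
    records = []
    if n_samples == 0:
        return None, records
    vertices = list(parameter_vertices)
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_samples):
        coords = vertices[i % len(vertices)]
        sub = int(rng.integers(0, 2**31 - 1))
        record = {"index": i, "coords": tuple(coords), "seed": sub,
                  "hysteretic": False, "failure": ""}
        try:
            params = pg.sample_parameters(coords, count=1, seed=sub)[0]
            system = build_hill_system(net, params, hill_n)
            hit = hysteretic_parameter_point(
                system, mode=mode, guesses=guesses, seed=sub, s_max=s_max,
                **continuation_kw,
            )
            record["hysteretic"] = bool(hit)
            hits += hit
        except Exception as exc:  # noqa: BLE001 - per-sample failures recorded
            record["failure"] = f"{type(exc).__name__}: {exc}"
        records.append(record)
    return 100.0 * hits / n_samples, records
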