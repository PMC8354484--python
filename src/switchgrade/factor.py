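"""Factor graphs: realizable parameter regions of a single network node.

For node ``n`` with in-edges from ``m_1 < ... < m_d`` and out-edges toward
``k_1 < ... < k_E`` the continuous parameters are the decay rate ``γ_n``,
per-in-edge low/high production rates ``ℓ_{n,m}`` and ``ℓ_{n,m}+δ_{n,m}``,
and per-out-edge thresholds ``θ_{k,n}`` (a basal rate ``β_n`` replaces the
production rates when there are no in-edges; a placeholder threshold stands
in when there are no out-edges).  A *region* is described combinatorially by

* a *threshold order*: the permutation of out-edge targets listing the
  thresholds in increasing value of ``γ_n·θ``, and
* a *binarization chain* ``B_1 ⊇ B_2 ⊇ ... ⊇ B_E``: ``B_i`` is the set of
  input switch-states whose production value exceeds the i-th threshold.

Each ``B_i`` must be an up-set of the polarity-adjusted order on input
states (raising an activating input can only raise production; raising a
repressing input can only lower it).  A combinatorial candidate is kept
only if the defining strict inequality system admits a positive *witness*
with a configurable margin; witnesses are found by linear programming for
pure-sum and pure-product production logic and by seeded slack-maximization
for mixed sum-times-product logic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog, minimize

from .networks import RegulatoryNetwork

__all__ = [
    "FactorVertex",
    "FactorGraph",
    "DegenerateParameterError",
    "enumerate_factor_graph",
    "production_values",
    "production_value_exprs",
    "is_realizable",
    "is_essential",
    "enumerate_up_sets",
    "count_nested_chains",
    "parameter_region_bound",
]

EPS_DEFAULT = 1e-6


class DegenerateParameterError(ValueError):
    """A numeric parameter point lies on a region boundary (tied values)."""


# ---------------------------------------------------------------------------
# input states, up-sets, chains
# ---------------------------------------------------------------------------

def input_states(d: int) -> tuple[tuple[int, ...], ...]:
    """All switch states for ``d`` in-edges (a single empty state for d=0)."""
    return tuple(itertools.product((0, 1), repeat=d))


def _polarity_le(s: tuple[int, ...], t: tuple[int, ...], signs: tuple[int, ...]) -> bool:
    """s <= t in the polarity-adjusted order (t has >= production potential)."""
    return all(
        (sb <= tb) if sign > 0 else (sb >= tb)
        for sb, tb, sign in zip(s, t, signs)
    )


def enumerate_up_sets(signs: tuple[int, ...]) -> tuple[frozenset, ...]:
    """All up-sets of the polarity-adjusted order on input states.

    For all-activator signs this is the set of monotone Boolean functions on
    d inputs (6 for d=2, 20 for d=3).
    """
    states = input_states(len(signs))
    ups = []
    for mask in itertools.product((0, 1), repeat=len(states)):
        subset = frozenset(s for s, b in zip(states, mask) if b)
        ok = all(
            (t in subset)
            for s in subset
            for t in states
            if _polarity_le(s, t, signs)
        )
        if ok:
            ups.append(subset)
    return tuple(ups)


def nested_chains(signs: tuple[int, ...], length: int) -> list[tuple[frozenset, ...]]:
    """All weakly decreasing chains ``B_1 ⊇ ... ⊇ B_length`` of up-sets."""
    ups = enumerate_up_sets(signs)
    chains: list[tuple[frozenset, ...]] = []

    def extend(prefix: tuple[frozenset, ...]):
        if len(prefix) == length:
            chains.append(prefix)
            return
        for u in ups:
            if not prefix or u <= prefix[-1]:
                extend(prefix + (u,))

    extend(())
    return chains


@lru_cache(maxsize=None)
def count_nested_chains(d: int, length: int) -> int:
    """Number of nested length-``length`` chains of up-sets of the d-cube."""
    return len(nested_chains((1,) * d, length))


def parameter_region_bound(net: RegulatoryNetwork) -> int:
    """Combinatorial upper bound on the number of parameter-graph vertices.

    Product over nodes of (chain count per threshold-order class) times the
    number of threshold orders.  Counts candidates before realizability
    pruning, hence an upper bound.
    """
    total = 1
    for n in range(net.n_nodes):
        m = max(1, net.out_degree(n))
        total *= count_nested_chains(net.in_degree(n), m) * math.factorial(m)
    return total


# ---------------------------------------------------------------------------
# production values
# ---------------------------------------------------------------------------

def production_values(
    net: RegulatoryNetwork, node: int, params: dict
) -> dict[tuple[int, ...], float]:
    """Numeric production value of ``node`` for every input switch-state.

    ``params`` maps keys ``("l", n, m)``, ``("d", n, m)`` (edge m→n) and
    ``("b", n)`` to positive floats.  Activating contributions are summed
    (``ℓ`` low, ``ℓ+δ`` high), then multiplied by each repressing factor
    (``ℓ+δ`` when the repressor is low, ``ℓ`` when high).
    """
    edges = net.in_edges(node)
    out = {}
    for s in input_states(len(edges)):
        if not edges:
            out[s] = float(params[("b", node)])
            continue
        total = 0.0
        have_act = False
        prod = 1.0
        for bit, (src, sign) in zip(s, edges):
            l = float(params[("l", node, src)])
            d = float(params[("d", node, src)])
            if sign > 0:
                have_act = True
                total += l + d * bit
            else:
                prod *= l if bit else l + d
        out[s] = (total if have_act else 1.0) * prod
    return out


def production_value_exprs(net: RegulatoryNetwork, node: int):
    """Symbolic (sympy) production value per input state; ``β`` if no in-edges."""
    import sympy

    edges = net.in_edges(node)
    out = {}
    for s in input_states(len(edges)):
        if not edges:
            out[s] = sympy.Symbol(f"beta_{node}", positive=True)
            continue
        terms = []
        factors = []
        for bit, (src, sign) in zip(s, edges):
            l = sympy.Symbol(f"l_{node}_{src}", positive=True)
            d = sympy.Symbol(f"d_{node}_{src}", positive=True)
            if sign > 0:
                terms.append(l + d if bit else l)
            else:
                factors.append(l if bit else l + d)
        expr = sympy.Add(*terms) if terms else sympy.Integer(1)
        for f in factors:
            expr = expr * f
        out[s] = sympy.expand(expr) if terms else expr
    return out


# ---------------------------------------------------------------------------
# realizability
# ---------------------------------------------------------------------------

def _k_profile(chain: Sequence[frozenset], states) -> dict:
    """state -> number of thresholds its production value must exceed."""
    return {s: sum(1 for B in chain if s in B) for s in states}


def _solve_sum(edges, node, order, chain, eps):
    """LP feasibility for pure-sum logic (all activators, or no in-edges)."""
    d = len(edges)
    m = len(order)
    states = input_states(d)
    kprof = _k_profile(chain, states)
    # variables: l_1..l_d, d_1..d_d (or b when d == 0), t_1..t_m, lam
    nvar = (2 * d if d else 1) + m + 1
    t0 = (2 * d if d else 1)
    ilam = nvar - 1

    def value_row(s):
        row = np.zeros(nvar)
        if d:
            for j, bit in enumerate(s):
                row[j] = 1.0
                if bit:
                    row[d + j] = 1.0
        else:
            row[0] = 1.0
        return row

    A, b = [], []

    def add_ge(lhs_row, rhs_row):  # lhs - rhs >= lam
        row = rhs_row - lhs_row
        row[ilam] += 1.0
        A.append(row)
        b.append(0.0)

    zero = np.zeros(nvar)
    for s in states:
        k = kprof[s]
        v = value_row(s)
        if k >= 1:
            t = zero.copy(); t[t0 + k - 1] = 1.0
            add_ge(v, t)
        if k < m:
            t = zero.copy(); t[t0 + k] = 1.0
            add_ge(t, v)
    # threshold ordering and positivity with margin
    prev = zero.copy()
    for i in range(m):
        t = zero.copy(); t[t0 + i] = 1.0
        add_ge(t, prev)
        prev = t
    for j in range(t0):
        e = zero.copy(); e[j] = 1.0
        add_ge(e, zero)

    c = np.zeros(nvar); c[ilam] = -1.0
    bounds = [(0, 100.0)] * (nvar - 1) + [(-1.0, 1.0)]
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    if not res.success or -res.fun < eps:
        return None
    x = res.x
    w = {("g", node): 1.0}
    if d:
        for j, (src, _) in enumerate(edges):
            w[("l", node, src)] = float(x[j])
            w[("d", node, src)] = float(x[d + j])
    else:
        w[("b", node)] = float(x[0])
    for i, tgt in enumerate(order):
        w[("t", tgt, node)] = float(x[t0 + i])
    return w


def _solve_product(edges, node, order, chain, eps):
    """LP feasibility in log space for pure-product logic (all repressors)."""
    d = len(edges)
    m = len(order)
    states = input_states(d)
    kprof = _k_profile(chain, states)
    # variables: rho_{j,0}, rho_{j,1} (log factor when bit=0 / bit=1),
    #            tau_1..tau_m (log of gamma*theta), lam
    nvar = 2 * d + m + 1
    t0 = 2 * d
    ilam = nvar - 1
    A, b = [], []
    zero = np.zeros(nvar)

    def add_ge(lhs, rhs):
        row = rhs - lhs
        row[ilam] += 1.0
        A.append(row)
        b.append(0.0)

    def value_row(s):
        row = zero.copy()
        for j, bit in enumerate(s):
            row[2 * j + bit] = 1.0
        return row

    for s in states:
        k = kprof[s]
        v = value_row(s)
        if k >= 1:
            t = zero.copy(); t[t0 + k - 1] = 1.0
            add_ge(v, t)
        if k < m:
            t = zero.copy(); t[t0 + k] = 1.0
            add_ge(t, v)
    for i in range(m - 1):
        lo = zero.copy(); lo[t0 + i] = 1.0
        hi = zero.copy(); hi[t0 + i + 1] = 1.0
        add_ge(hi, lo)
    for j in range(d):  # delta > 0: factor at bit=0 strictly above bit=1
        hi = zero.copy(); hi[2 * j] = 1.0
        lo = zero.copy(); lo[2 * j + 1] = 1.0
        add_ge(hi, lo)

    c = np.zeros(nvar); c[ilam] = -1.0
    bounds = [(-6.0, 6.0)] * (nvar - 1) + [(-1.0, 0.7)]
    res = linprog(c, A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
                  method="highs")
    if not res.success or -res.fun < eps:
        return None
    x = res.x
    w = {("g", node): 1.0}
    for j, (src, _) in enumerate(edges):
        hi = math.exp(x[2 * j]); lo = math.exp(x[2 * j + 1])
        w[("l", node, src)] = lo
        w[("d", node, src)] = hi - lo
    for i, tgt in enumerate(order):
        w[("t", tgt, node)] = math.exp(x[t0 + i])
    return w


def _solve_mixed(edges, node, order, chain, eps, seed, n_starts):
    """Seeded slack maximization (SLSQP) for mixed sum-times-product logic.

    Returns ``(witness, status)`` where status is "ok", "infeasible" or
    "undecided" (no solver start converged).
    """
    acts = [j for j, (_, sign) in enumerate(edges) if sign > 0]
    reps = [j for j, (_, sign) in enumerate(edges) if sign < 0]
    d = len(edges)
    m = len(order)
    states = input_states(d)
    kprof = _k_profile(chain, states)
    # z = [log l_a..., log d_a..., rho_{r,0}, rho_{r,1}..., tau_1..m, lam]
    na = len(acts)
    nr = len(reps)
    t0 = 2 * na + 2 * nr
    nvar = t0 + m + 1
    ilam = nvar - 1

    def log_value(z, s):
        tot = 0.0
        for a_i, j in enumerate(acts):
            tot += math.exp(z[a_i])
            if s[j]:
                tot += math.exp(z[na + a_i])
        v = math.log(tot) if na else 0.0
        for r_i, j in enumerate(reps):
            v += z[2 * na + 2 * r_i + (1 if s[j] else 0)]
        return v

    cons = []
    for s in states:
        k = kprof[s]
        if k >= 1:
            cons.append(lambda z, s=s, k=k: log_value(z, s) - z[t0 + k - 1] - z[ilam])
        if k < m:
            cons.append(lambda z, s=s, k=k: z[t0 + k] - log_value(z, s) - z[ilam])
    for i in range(m - 1):
        cons.append(lambda z, i=i: z[t0 + i + 1] - z[t0 + i] - z[ilam])
    for r_i in range(nr):
        cons.append(lambda z, r=r_i: z[2 * na + 2 * r] - z[2 * na + 2 * r + 1] - z[ilam])

    bounds = [(-6.0, 6.0)] * (nvar - 1) + [(-1.0, 0.7)]
    rng = np.random.default_rng(seed)
    converged = False
    for _ in range(n_starts):
        z0 = np.concatenate([rng.uniform(-2, 2, size=nvar - 1), [0.0]])
        try:
            res = minimize(
                lambda z: -z[ilam], z0, method="SLSQP", bounds=bounds,
                constraints=[{"type": "ineq", "fun": c} for c in cons],
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except (ValueError, FloatingPointError):
            continue
        if not res.success:
            continue
        converged = True
        z = res.x
        if z[ilam] < eps:
            continue
        w = {("g", node): 1.0}
        for a_i, j in enumerate(acts):
            src = edges[j][0]
            w[("l", node, src)] = math.exp(z[a_i])
            w[("d", node, src)] = math.exp(z[na + a_i])
        for r_i, j in enumerate(reps):
            src = edges[j][0]
            hi = math.exp(z[2 * na + 2 * r_i])
            lo = math.exp(z[2 * na + 2 * r_i + 1])
            w[("l", node, src)] = lo
            w[("d", node, src)] = hi - lo
        for i, tgt in enumerate(order):
            w[("t", tgt, node)] = math.exp(z[t0 + i])
        if _verify_witness(edges, node, order, chain, w, eps):
            return w, "ok"
    return None, ("infeasible" if converged else "undecided")


def _verify_witness(edges, node, order, chain, w, eps):
    """Exact re-check: witness separates every state/threshold pair with margin."""
    from . import networks as _n  # cheap; avoids circular type imports

    net = _fake_net_for(edges, node, order)
    vals = production_values(net, node, w)
    g = w[("g", node)]
    ts = [g * w[("t", tgt, node)] for tgt in order]
    kprof = _k_profile(chain, vals.keys())
    scale = max(max(ts), max(vals.values()))
    for s, v in vals.items():
        k = kprof[s]
        if k >= 1 and not v > ts[k - 1] + eps * scale:
            return False
        if k < len(ts) and not v < ts[k] - eps * scale:
            return False
    return all(ts[i] + eps * scale < ts[i + 1] for i in range(len(ts) - 1))


def _fake_net_for(edges, node, order):
    """Minimal network stub whose ``in_edges(node)`` matches ``edges``."""
    n = max([node] + [src for src, _ in edges] + [t for t in order if t is not None]) + 1
    from .networks import RegulatoryNetwork

    mat = [[0] * n for _ in range(n)]
    for src, sign in edges:
        mat[node][src] = sign
    return RegulatoryNetwork(tuple(f"x{i}" for i in range(n)),
                             tuple(tuple(r) for r in mat))


def is_realizable(
    net: RegulatoryNetwork,
    node: int,
    order: tuple,
    chain: tuple,
    eps: float = EPS_DEFAULT,
    seed: int = 0,
    mixed_starts: int = 20,
):
    """Decide realizability of a (threshold order, chain) candidate.

    Returns ``(witness, status)``: witness is a positive parameter dict (or
    None), status is ``"ok"``, ``"infeasible"``, ``"invalid-chain"`` or
    ``"undecided"`` (mixed-logic solver failed to converge from any start).
    """
    edges = net.in_edges(node)
    signs = tuple(sign for _, sign in edges)
    states = input_states(len(edges))
    ups = set(enumerate_up_sets(signs))
    if any(B not in ups for B in chain):
        return None, "invalid-chain"
    if any(not chain[i] >= chain[i + 1] for i in range(len(chain) - 1)):
        return None, "invalid-chain"

    has_act = any(s > 0 for s in signs)
    has_rep = any(s < 0 for s in signs)
    if not edges or (has_act and not has_rep):
        w = _solve_sum(edges, node, order, chain, eps)
    elif has_rep and not has_act:
        w = _solve_product(edges, node, order, chain, eps)
    else:
        return _solve_mixed(edges, node, order, chain, eps, seed, mixed_starts)
    return (w, "ok") if w is not None else (None, "infeasible")


# ---------------------------------------------------------------------------
# factor graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorVertex:
    """One realizable parameter region of a single node."""

    node: int
    order: tuple            # out-edge targets by increasing threshold (None = placeholder)
    chain: tuple            # nested frozensets of input states
    witness: dict = field(compare=False, hash=False, repr=False)
    essential: bool = field(compare=False, hash=False, default=False)

    @property
    def key(self):
        return (self.order, self.chain)

    def k_of(self, state) -> int:
        """Number of thresholds the production value at ``state`` exceeds."""
        return sum(1 for B in self.chain if state in B)


class FactorGraph:
    """All realizable regions of one node, with adjacency and the path order."""

    def __init__(self, net: RegulatoryNetwork, node: int,
                 vertices: list[FactorVertex], undecided: int):
        self.net = net
        self.node = node
        self.vertices = vertices
        self.undecided = undecided
        self._index = {v.key: i for i, v in enumerate(vertices)}
        self.adjacency = self._build_adjacency()

    def __len__(self):
        return len(self.vertices)

    # -- structure -------------------------------------------------------
    def _build_adjacency(self) -> set[tuple[int, int]]:
        edges = set()
        n = len(self.vertices)
        for i in range(n):
            vi = self.vertices[i]
            for j in range(i + 1, n):
                vj = self.vertices[j]
                if self._adjacent(vi, vj):
                    edges.add((i, j))
        return edges

    @staticmethod
    def _adjacent(u: FactorVertex, w: FactorVertex) -> bool:
        if u.order == w.order:
            # exactly one state moved in exactly one chain entry
            diffs = [
                (len(a ^ b))
                for a, b in zip(u.chain, w.chain)
            ]
            return sum(diffs) == 1
        # adjacent transposition of the threshold order with matching chain
        if u.chain != w.chain:
            return False
        ou, ow = u.order, w.order
        pos = [i for i, (a, b) in enumerate(zip(ou, ow)) if a != b]
        if len(pos) != 2 or pos[1] != pos[0] + 1:
            return False
        i = pos[0]
        if not (ou[i] == ow[i + 1] and ou[i + 1] == ow[i]):
            return False
        # crossing t_i = t_{i+1} is codimension one only if the two
        # thresholds binarize identically
        return u.chain[i] == u.chain[i + 1]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    # -- the signal (path) partial order --------------------------------
    def signal_le(self, i: int, j: int) -> bool:
        """Region ``j`` is reachable from ``i`` by raising the input signal.

        Within a fixed threshold order, larger above-sets mean the node's
        production clears more of its thresholds; the minimal vertex has all
        binarization sets empty, the maximal all-full.
        """
        u, w = self.vertices[i], self.vertices[j]
        return u.order == w.order and all(a <= b for a, b in zip(u.chain, w.chain))

    def class_indices(self, order: tuple) -> list[int]:
        return [i for i, v in enumerate(self.vertices) if v.order == order]

    def identity_order(self) -> tuple:
        out = self.net.out_edges(self.node)
        return tuple(out) if out else (None,)

    def minimal_vertex(self, order: tuple | None = None) -> int:
        order = order or self.identity_order()
        cands = [i for i in self.class_indices(order)
                 if all(not B for B in self.vertices[i].chain)]
        assert len(cands) == 1
        return cands[0]

    def maximal_vertex(self, order: tuple | None = None) -> int:
        order = order or self.identity_order()
        states = frozenset(input_states(self.net.in_degree(self.node)))
        cands = [i for i in self.class_indices(order)
                 if all(B == states for B in self.vertices[i].chain)]
        assert len(cands) == 1
        return cands[0]

    def essential_indices(self) -> list[int]:
        return [i for i, v in enumerate(self.vertices) if v.essential]

    # -- numeric classification ------------------------------------------
    def classify_params(self, params: dict) -> int:
        """Map a positive numeric parameter point to its region index."""
        node = self.node
        out = self.net.out_edges(node)
        targets = tuple(out) if out else (None,)
        g = float(params[("g", node)])
        scaled = [(g * float(params[("t", tgt, node)]), tgt) for tgt in targets]
        if len({t for t, _ in scaled}) != len(scaled):
            raise DegenerateParameterError("tied thresholds")
        scaled.sort()
        order = tuple(tgt for _, tgt in scaled)
        ts = [t for t, _ in scaled]
        vals = production_values(self.net, node, params)
        if any(math.isclose(v, t, rel_tol=1e-12) for v in vals.values() for t in ts):
            raise DegenerateParameterError("production value equals a threshold")
        chain = tuple(
            frozenset(s for s, v in vals.items() if v > t) for t in ts
        )
        key = (order, chain)
        if key not in self._index:
            raise KeyError(f"parameter point maps to an unenumerated region {key}")
        return self._index[key]

    # -- export -----------------------------------------------------------
    def to_dict(self) -> dict:
        def mask(B):
            states = input_states(self.net.in_degree(self.node))
            return sum(1 << i for i, s in enumerate(states) if s in B)

        return {
            "node": self.node,
            "vertices": [
                {
                    "id": i,
                    "order": [(-1 if t is None else t) for t in v.order],
                    "chain": [mask(B) for B in v.chain],
                    "essential": v.essential,
                    "witness": {self._param_name(k): val for k, val in v.witness.items()},
                }
                for i, v in enumerate(self.vertices)
            ],
            "adjacency": sorted(map(list, self.adjacency)),
            "undecided": self.undecided,
        }

    @staticmethod
    def _param_name(key) -> str:
        tag = key[0]
        if tag == "g":
            return f"gamma[{key[1]}]"
        if tag == "b":
            return f"beta[{key[1]}]"
        if tag == "t":
            tgt = "T" if key[1] is None else key[1]
            return f"t[{tgt}][{key[2]}]"
        return f"{tag}[{key[1]}][{key[2]}]"


def is_essential(net: RegulatoryNetwork, node: int, vertex: FactorVertex) -> bool:
    """Every out-threshold is crossed and every in-edge separates states."""
    d = net.in_degree(node)
    states = input_states(d)
    all_states = frozenset(states)
    for B in vertex.chain:
        if not B or B == all_states:
            return False
    for j in range(d):
        sep = False
        for s in states:
            if s[j] == 0:
                t = s[:j] + (1,) + s[j + 1:]
                if vertex.k_of(s) != vertex.k_of(t):
                    sep = True
                    break
        if not sep:
            return False
    return True


def enumerate_factor_graph(
    net: RegulatoryNetwork,
    node: int,
    classes: str = "all",
    eps: float = EPS_DEFAULT,
    seed: int = 0,
    mixed_starts: int = 20,
) -> FactorGraph:
    """Enumerate the factor graph of ``node``.

    ``classes`` is ``"all"`` (every threshold-order permutation) or
    ``"identity"`` (only the order listing out-edge targets by index, the
    class used by path-based scoring).
    """
    edges = net.in_edges(node)
    signs = tuple(sign for _, sign in edges)
    out = net.out_edges(node)
    targets = tuple(out) if out else (None,)
    m = len(targets)
    if len(edges) > 4 or m > 4:
        raise ValueError("factor graphs support at most 4 in-edges and 4 out-edges")

    if classes == "identity":
        orders: Iterable[tuple] = [targets]
    elif classes == "all":
        orders = list(itertools.permutations(targets))
    else:
        raise ValueError(f"unknown classes selector {classes!r}")

    chains = nested_chains(signs, m)
    vertices: list[FactorVertex] = []
    undecided = 0
    for order in orders:
        for chain in chains:
            w, status = is_realizable(net, node, order, chain, eps=eps,
                                      seed=seed, mixed_starts=mixed_starts)
            if status == "undecided":
                undecided += 1
                continue
            if w is None:
                continue
            v = FactorVertex(node=node, order=order, chain=chain, witness=w)
            object.__setattr__(v, "essential", is_essential(net, node, v))
            vertices.append(v)
    return FactorGraph(net, node, vertices, undecided)
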