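"""Parameter graphs: products of factor graphs, regions, and sampling.

A parameter-graph vertex is a tuple of factor-graph vertex indices, one per
node.  Because the continuous parameters of different nodes never appear in
the same defining inequality, the full decomposition of parameter space is
the Cartesian product of the per-node decompositions, and parameter-graph
edges change exactly one coordinate along a factor-graph edge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .factor import (
    FactorGraph,
    enumerate_factor_graph,
    production_values,
    input_states,
)
from .networks import RegulatoryNetwork

__all__ = [
    "ParameterGraph",
    "ParameterRegion",
    "build_parameter_graph",
    "SamplerError",
]


class SamplerError(RuntimeError):
    """Raised when region sampling exhausts its rejection budget."""

    def __init__(self, message, region_id=None):
        super().__init__(message)
        self.region_id = region_id


@dataclass
class ParameterRegion:
    """Explicit open region of parameter space for one parameter-graph vertex.

    ``inequalities`` are strings in the grammar ``lhs < rhs`` over the symbols
    ``gamma[n]``, ``l[n][m]``, ``d[n][m]``, ``t[m][n]`` and ``beta[n]``
    (plus ``t[T][n]`` for the placeholder threshold of a node without
    out-edges).  ``witness`` is a positive parameter vector satisfying every
    inequality strictly.
    """

    coords: tuple
    inequalities: list[str]
    witness: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "coords": list(self.coords),
                "inequalities": self.inequalities,
                "witness": {ParameterGraph.param_name(k): v
                            for k, v in sorted(self.witness.items(),
                                               key=lambda kv: str(kv[0]))},
            },
            indent=2,
        )


class ParameterGraph:
    """Product of the per-node factor graphs of a network."""

    def __init__(self, net: RegulatoryNetwork, factors: list[FactorGraph]):
        self.net = net
        self.factors = factors

    @property
    def size(self) -> int:
        return math.prod(len(f) for f in self.factors)

    def vertices(self) -> Iterable[tuple]:
        import itertools

        return itertools.product(*(range(len(f)) for f in self.factors))

    def neighbors(self, coords: tuple, nodes: Sequence[int] | None = None):
        """Product-graph neighbors of ``coords`` moving only listed nodes."""
        nodes = range(self.net.n_nodes) if nodes is None else nodes
        for n in nodes:
            for j in self.factors[n].neighbors(coords[n]):
                yield coords[:n] + (j,) + coords[n + 1:]

    # -- essential machinery ---------------------------------------------
    def essential_subgraph(self, nodes: Sequence[int]) -> list[tuple]:
        """All vertices whose coordinates for ``nodes`` are essential.

        With an empty node subset this is the full vertex set (materialized;
        callers should restrict nodes for large graphs).
        """
        import itertools

        pools = []
        for n in range(self.net.n_nodes):
            if n in nodes:
                pools.append(self.factors[n].essential_indices())
            else:
                pools.append(list(range(len(self.factors[n]))))
        return [tuple(c) for c in itertools.product(*pools)]

    def one_edge_neighborhood(
        self, vertex_set: Iterable[tuple], nodes: Sequence[int] | None = None
    ) -> set[tuple]:
        """Closed distance-<=1 neighborhood moving only coordinates of ``nodes``."""
        out = set()
        for v in vertex_set:
            out.add(v)
            out.update(self.neighbors(v, nodes))
        return out

    # -- explicit regions --------------------------------------------------
    @staticmethod
    def param_name(key) -> str:
        tag = key[0]
        if tag == "g":
            return f"gamma[{key[1]}]"
        if tag == "b":
            return f"beta[{key[1]}]"
        if tag == "t":
            tgt = "T" if key[1] is None else key[1]
            return f"t[{tgt}][{key[2]}]"
        return f"{tag}[{key[1]}][{key[2]}]"

    def region(self, coords: tuple) -> ParameterRegion:
        """Assemble the full inequality description and witness of a vertex."""
        ineqs: list[str] = []
        witness: dict = {}
        name = self.param_name
        for n, fg in enumerate(self.factors):
            v = fg.vertices[coords[n]]
            witness.update(v.witness)
            order = v.order
            g = f"{name(('g', n))}*"
            # positivity
            for key in v.witness:
                ineqs.append(f"0 < {name(key)}")
            # threshold ordering
            for a, b in zip(order, order[1:]):
                ineqs.append(
                    f"{g}{name(('t', a, n))} < {g}{name(('t', b, n))}"
                )
            # binarization inequalities
            edges = self.net.in_edges(n)
            for s in input_states(len(edges)):
                expr = self._value_expr(n, edges, s)
                k = v.k_of(s)
                if k >= 1:
                    ineqs.append(f"{g}{name(('t', order[k - 1], n))} < {expr}")
                if k < len(order):
                    ineqs.append(f"{expr} < {g}{name(('t', order[k], n))}")
        return ParameterRegion(coords=coords, inequalities=ineqs, witness=witness)

    def _value_expr(self, n: int, edges, s) -> str:
        name = self.param_name
        if not edges:
            return name(("b", n))
        terms = []
        factors = []
        for bit, (src, sign) in zip(s, edges):
            l = name(("l", n, src))
            d = name(("d", n, src))
            if sign > 0:
                terms.append(f"{l} + {d}" if bit else l)
            else:
                factors.append(l if bit else f"({l} + {d})")
        expr = " + ".join(terms)
        if expr and factors and "+" in expr:
            expr = f"({expr})"
        return "*".join(x for x in [expr] + factors if x) or "1"

    # -- numeric sampling --------------------------------------------------
    def check_params(self, coords: tuple, params: dict, eps: float = 1e-6) -> bool:
        """True iff ``params`` lies in the region of ``coords`` with margin."""
        for n, fg in enumerate(self.factors):
            v = fg.vertices[coords[n]]
            g = params[("g", n)]
            ts = [g * params[("t", tgt, n)] for tgt in v.order]
            vals = production_values(self.net, n, params)
            scale = max(max(ts), max(vals.values()))
            if any(p <= 0 for p in params.values()):
                return False
            for a, b in zip(ts, ts[1:]):
                if not a + eps * scale < b:
                    return False
            for s, val in vals.items():
                k = v.k_of(s)
                if k >= 1 and not val > ts[k - 1] + eps * scale:
                    return False
                if k < len(ts) and not val < ts[k] - eps * scale:
                    return False
        return True

    # -- node-wise linear systems for sampling ----------------------------
    def _node_system(self, n: int, vertex_idx: int, eps: float, box_hi: float):
        """Linear inequality system A·x ≤ b for one node's region.

        For sum logic (and no-in-edge nodes) the variables are the rates and
        thresholds themselves; for product logic their logarithms.  Mixed
        sum-times-product nodes are not linear; ``None`` is returned and the
        caller falls back to a witness-anchored walk.
        """
        from .factor import input_states as _states

        fg = self.factors[n]
        v = fg.vertices[vertex_idx]
        edges = self.net.in_edges(n)
        signs = [s for _, s in edges]
        has_act = any(s > 0 for s in signs)
        has_rep = any(s < 0 for s in signs)
        if has_act and has_rep:
            return None
        logspace = has_rep
        m = len(v.order)
        d = len(edges)
        if not edges:
            keys = [("b", n)] + [("t", tgt, n) for tgt in v.order]
        elif logspace:
            keys = []
            for src, _ in edges:
                keys += [("l", n, src), ("d", n, src)]
            keys += [("t", tgt, n) for tgt in v.order]
        else:
            keys = [("l", n, src) for src, _ in edges]
            keys += [("d", n, src) for src, _ in edges]
            keys += [("t", tgt, n) for tgt in v.order]
        nv = len(keys)
        t0 = nv - m
        rows, rhs = [], []

        def le(row, b):  # row·x ≤ b - eps
            rows.append(row)
            rhs.append(b - eps)

        def value_row(s):
            row = np.zeros(nv)
            if not edges:
                row[0] = 1.0
            elif logspace:
                # variables hold log(l) and log(l+d) per edge:
                # keys l -> log low factor, d -> log high factor
                for j, bit in enumerate(s):
                    row[2 * j + (0 if bit else 1)] = 1.0
            else:
                for j, bit in enumerate(s):
                    row[j] = 1.0
                    if bit:
                        row[d + j] = 1.0
            return row

        for s in _states(d):
            k = v.k_of(s)
            row = value_row(s)
            if k >= 1:
                t = np.zeros(nv); t[t0 + k - 1] = 1.0
                le(t - row, 0.0)          # t_{k} < value
            if k < m:
                t = np.zeros(nv); t[t0 + k] = 1.0
                le(row - t, 0.0)          # value < t_{k+1}
        for i in range(m - 1):
            row = np.zeros(nv); row[t0 + i] = 1.0; row[t0 + i + 1] = -1.0
            le(row, 0.0)
        if logspace:
            for j in range(d):           # low factor strictly below high one
                row = np.zeros(nv); row[2 * j] = 1.0; row[2 * j + 1] = -1.0
                le(row, 0.0)
            lo_b, hi_b = math.log(0.02), math.log(box_hi)
        else:
            lo_b, hi_b = 0.0, box_hi
        for j in range(nv):
            row = np.zeros(nv); row[j] = 1.0
            le(row, hi_b)
            row = np.zeros(nv); row[j] = -1.0
            le(row, -lo_b)
        return keys, np.array(rows), np.array(rhs), logspace

    @staticmethod
    def _hit_and_run(A, b, x0, rng, steps):
        x = x0.copy()
        nv = len(x)
        for _ in range(steps):
            u = rng.normal(size=nv)
            u /= np.linalg.norm(u)
            Au = A @ u
            slack = b - A @ x
            hi = np.inf
            lo = -np.inf
            pos = Au > 1e-14
            neg = Au < -1e-14
            if pos.any():
                hi = np.min(slack[pos] / Au[pos])
            if neg.any():
                lo = np.max(slack[neg] / Au[neg])
            if not (np.isfinite(hi) and np.isfinite(lo)) or hi <= lo:
                continue
            x = x + rng.uniform(lo, hi) * u
        return x

    def _interior_point(self, A, b):
        """Max-slack (Chebyshev-like) interior point of A·x ≤ b."""
        from scipy.optimize import linprog

        nv = A.shape[1]
        c = np.zeros(nv + 1)
        c[-1] = -1.0
        A2 = np.hstack([A, np.ones((A.shape[0], 1))])
        res = linprog(c, A_ub=A2, b_ub=b, bounds=[(None, None)] * (nv + 1),
                      method="highs")
        if not res.success or res.x[-1] <= 0:
            return None
        return res.x[:nv]

    def sample_parameters(
        self,
        coords: tuple,
        count: int,
        seed: int,
        eps: float = 1e-6,
        box_hi: float = 6.0,
        walk_steps: int = 30,
        max_rejections: int = 10_000,
    ) -> list[dict]:
        """Draw ``count`` positive parameter vectors from a region.

        Decay rates are fixed to 1.  Per node, the region is a polytope in
        the rates/thresholds (or their logs, for product logic) intersected
        with an O(1) box; samples are produced by seeded hit-and-run from a
        max-slack interior point, so every returned vector is a certified
        member of the region.  Mixed-logic nodes fall back to a rejection
        random walk anchored at the stored witness.  Membership, not
        uniformity, is the guarantee.
        """
        if count == 0:
            return []
        rng = np.random.default_rng(seed)
        systems = []
        for n in range(self.net.n_nodes):
            sysn = self._node_system(n, coords[n], eps, box_hi)
            if sysn is None:
                systems.append(None)
                continue
            keys, A, b, logspace = sysn
            x0 = self._interior_point(A, b)
            if x0 is None:
                raise SamplerError(
                    f"region of node {n} has no interior point in the box",
                    region_id=coords,
                )
            systems.append((keys, A, b, logspace, x0))

        samples = []
        rejections = 0
        for _ in range(count):
            params = {("g", n): 1.0 for n in range(self.net.n_nodes)}
            for n in range(self.net.n_nodes):
                if systems[n] is not None:
                    keys, A, b, logspace, x0 = systems[n]
                    x = self._hit_and_run(A, b, x0, rng, walk_steps)
                    vals = np.exp(x) if logspace else x
                    if logspace:
                        # stored pair is (log low, log high); convert to (l, d)
                        d_edges = self.net.in_edges(n)
                        for j, (src, _) in enumerate(d_edges):
                            lo = vals[2 * j]
                            hi = vals[2 * j + 1]
                            params[("l", n, src)] = float(lo)
                            params[("d", n, src)] = float(hi - lo)
                        for i, tgt in enumerate(
                                self.factors[n].vertices[coords[n]].order):
                            params[("t", tgt, n)] = float(
                                vals[2 * len(d_edges) + i])
                    else:
                        for key, val in zip(keys, vals):
                            params[key] = float(val)
                else:
                    # witness-anchored rejection walk for mixed logic
                    w = dict(self.factors[n].vertices[coords[n]].witness)
                    nkeys = sorted(
                        [k for k in w if k[0] != "g"], key=str)
                    z = np.log([w[k] for k in nkeys])
                    good = z.copy()
                    for _ in range(walk_steps):
                        prop = z + rng.normal(0.0, 0.3, size=z.shape)
                        cand = dict(w)
                        cand.update(
                            {k: float(math.exp(v))
                             for k, v in zip(nkeys, prop)})
                        if self._check_node(n, coords[n], cand, eps):
                            z = prop
                            good = z
                        else:
                            rejections += 1
                            if rejections > max_rejections:
                                raise SamplerError(
                                    f"sampler exceeded {max_rejections} "
                                    "rejections", region_id=coords)
                    for k, v in zip(nkeys, good):
                        params[k] = float(math.exp(v))
            if not self.check_params(coords, params, eps * 0.01):
                raise SamplerError(
                    "sampled point failed certification", region_id=coords)
            samples.append(params)
        return samples

    def _check_node(self, n: int, vertex_idx: int, params: dict,
                    eps: float) -> bool:
        fg = self.factors[n]
        v = fg.vertices[vertex_idx]
        g = params.get(("g", n), 1.0)
        ts = [g * params[("t", tgt, n)] for tgt in v.order]
        vals = production_values(self.net, n, params)
        scale = max(max(ts), max(vals.values()))
        for a, b in zip(ts, ts[1:]):
            if not a + eps * scale < b:
                return False
        for s, val in vals.items():
            k = v.k_of(s)
            if k >= 1 and not val > ts[k - 1] + eps * scale:
                return False
            if k < len(ts) and not val < ts[k] - eps * scale:
                return False
        return True

    def classify(self, params: dict) -> tuple:
        """Map a numeric parameter vector to its parameter-graph vertex."""
        return tuple(fg.classify_params(params) for fg in self.factors)


def samples_to_dataframe(samples):
    """Tabulate sampled parameter vectors, one named column per parameter."""
    import pandas as pd

    rows = [
        {ParameterGraph.param_name(k): v for k, v in s.items()}
        for s in samples
    ]
    df = pd.DataFrame(rows)
    return df.reindex(sorted(df.columns), axis=1)


def build_parameter_graph(
    net: RegulatoryNetwork,
    classes: str | Sequence[str] = "all",
    eps: float = 1e-6,
    seed: int = 0,
    mixed_starts: int = 20,
) -> ParameterGraph:
    """Enumerate every factor graph and assemble the product graph.

    ``classes`` may be a single selector (``"all"`` / ``"identity"``) applied
    to every node, or a per-node sequence (path-based scoring typically uses
    ``"identity"`` for the input node and ``"all"`` elsewhere).
    """
    if isinstance(classes, str):
        classes = [classes] * net.n_nodes
    factors = [
        enumerate_factor_graph(net, n, classes=classes[n], eps=eps, seed=seed,
                               mixed_starts=mixed_starts)
        for n in range(net.n_nodes)
    ]
    return ParameterGraph(net, factors)
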