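"""Hysteresis scoring over monotone paths in the input node's factor graph.

A continuous ramp of the external signal to the input node traces a
monotone path through that node's factor graph (the binarization sets only
grow as production clears more thresholds).  A path *exhibits ascending
hysteresis* for a fixed choice of the remaining nodes' regions if the
attractor structure along it reads: low-output stable state at the start,
high-output at the end, and both simultaneously (bistability) at some
strictly intermediate vertex.  Scores aggregate this predicate over
(path, parameter-vertex) pairs; the *perturbed* variant replaces the
essential parameter set by its closed one-edge neighborhood, and their
ratio defines robustness (fragile when ≤ 0.5).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .dynamics import build_stg, morse_graph
from .networks import RegulatoryNetwork, canonical_id, node_consistency
from .pgraph import ParameterGraph, build_parameter_graph

__all__ = [
    "SignalPath",
    "ScoreReport",
    "signal_dag",
    "count_paths",
    "enumerate_paths",
    "hysteresis_predicate",
    "hysteresis_score",
    "robustness_and_classification",
    "screen",
]

FRAGILE_CUTOFF = 0.5


# ---------------------------------------------------------------------------
# monotone paths in the input node's factor graph
# ---------------------------------------------------------------------------

def signal_dag(pg: ParameterGraph, node: int = 0, order: tuple | None = None):
    """DAG of signal-monotone factor-graph moves within one threshold-order
    class: an edge u→w for each adjacency where w's binarization strictly
    contains u's."""
    fg = pg.factors[node]
    order = order or fg.identity_order()
    idx = fg.class_indices(order)
    idxset = set(idx)
    succ = {i: [] for i in idx}
    for a, b in fg.adjacency:
        if a in idxset and b in idxset:
            if fg.signal_le(a, b):
                succ[a].append(b)
            elif fg.signal_le(b, a):
                succ[b].append(a)
    return succ


def count_paths(succ: dict, kind: str = "partial",
                source: int | None = None, target: int | None = None) -> int:
    """Exact path counts by dynamic programming over the DAG.

    ``partial``: paths with at least three vertices, any endpoints.
    ``full``: paths from ``source`` to ``target`` with at least three vertices.
    """
    if kind == "partial":
        total = {}

        def f(u):
            if u not in total:
                total[u] = 1 + sum(f(w) for w in succ[u])
            return total[u]

        all_paths = sum(f(u) for u in succ)
        n_vertices = len(succ)
        n_edges = sum(len(v) for v in succ.values())
        return all_paths - n_vertices - n_edges
    if kind == "full":
        memo = {}

        def g(u):
            if u == target:
                return 1
            if u not in memo:
                memo[u] = sum(g(w) for w in succ[u])
            return memo[u]

        if source == target:
            return 0
        n = g(source)
        # subtract a possible two-vertex path (direct edge source→target)
        if target in succ[source]:
            n -= 1
        return n
    raise ValueError(f"unknown path kind {kind!r}")


def enumerate_paths(succ: dict, kind: str = "partial",
                    source: int | None = None, target: int | None = None,
                    cap: int = 100_000):
    """Explicit path enumeration (for small factor graphs / cross-checks)."""
    out = []

    def walk(path):
        if len(out) > cap:
            raise RuntimeError(f"path enumeration exceeded cap {cap}")
        u = path[-1]
        if kind == "partial" and len(path) >= 3:
            out.append(tuple(path))
        if kind == "full" and u == target and len(path) >= 3:
            out.append(tuple(path))
            return
        for w in succ[u]:
            walk(path + [w])

    starts = [source] if kind == "full" else list(succ)
    for s in starts:
        walk([s])
    return out


@dataclass(frozen=True)
class SignalPath:
    vertices: tuple
    kind: str  # "partial" | "full"


# ---------------------------------------------------------------------------
# the hysteresis predicate
# ---------------------------------------------------------------------------

def _vertex_flags(pg: ParameterGraph, node: int, v0_indices: Sequence[int],
                  rest: tuple, mode: str, strict_ends: bool):
    """Per input-node region: (start_ok, end_ok, bistable) flags.

    ``rest`` fixes the factor-vertex index of every node except ``node``.
    Ascending: start needs a minimal FP with output coordinate 0, end one
    with output coordinate > 0, bistable needs both at once.  Descending
    mirrors start and end.  ``strict_ends`` additionally demands monostable
    endpoints (no high FP at the start, no low FP at the end).
    """
    net = pg.net
    out_node = net.output_node
    flags = {}
    for v0 in v0_indices:
        coords = rest[:node] + (v0,) + rest[node:]
        fvs = [pg.factors[n].vertices[coords[n]] for n in range(net.n_nodes)]
        mg = morse_graph(build_stg(net, fvs))
        labels = [mg.fp_labels[i] for i in mg.minimal if i in mg.fp_labels]
        low = any(lab[out_node] == 0 for lab in labels)
        high = any(lab[out_node] > 0 for lab in labels)
        if mode == "ascending":
            start_ok, end_ok = low, high
        elif mode == "descending":
            start_ok, end_ok = high, low
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if strict_ends:
            start_ok = start_ok and not (high if mode == "ascending" else low)
            end_ok = end_ok and not (low if mode == "ascending" else high)
        flags[v0] = (start_ok, end_ok, low and high)
    return flags


def hysteresis_predicate(pg: ParameterGraph, path: Sequence[int], rest: tuple,
                         mode: str = "ascending", node: int = 0,
                         strict_ends: bool = True) -> bool:
    """Evaluate the hysteresis predicate on one explicit path."""
    if len(path) < 3:
        raise ValueError("hysteresis requires paths of at least three vertices")
    flags = _vertex_flags(pg, node, sorted(set(path)), rest, mode, strict_ends)
    start_ok, _, _ = flags[path[0]]
    _, end_ok, _ = flags[path[-1]]
    return (
        start_ok
        and end_ok
        and any(flags[v][2] for v in path[1:-1])
    )


def _count_hysteretic(succ: dict, flags: dict, kind: str,
                      source: int | None, target: int | None) -> int:
    """DP count of hysteretic paths given per-vertex flags."""
    if kind == "full":
        if source == target or not flags[source][0] or not flags[target][1]:
            return 0
        total = count_paths(succ, "full", source, target)

        memo = {}

        def avoid(u):  # paths u→target whose interior avoids bistable vertices
            if u == target:
                return 1
            if u not in memo:
                memo[u] = sum(
                    avoid(w)
                    for w in succ[u]
                    if w == target or not flags[w][2]
                )
            return memo[u]

        n_avoid = avoid(source)
        if target in succ[source]:
            n_avoid -= 1  # the two-vertex path is excluded from both counts
        return total - n_avoid

    # partial paths: suffix DP over (vertex, bistable-seen-in-interior)
    memo: dict[tuple, int] = {}

    def suffix(v, seen):
        # v is the current interior vertex; count valid continuations
        key = (v, seen)
        if key not in memo:
            n = 0
            for w in succ[v]:
                if flags[w][1] and seen:
                    n += 1                      # stop: w is the end vertex
                n += suffix(w, seen or flags[w][2])
            memo[key] = n
        return memo[key]

    total = 0
    for u in succ:
        if not flags[u][0]:
            continue
        for m in succ[u]:
            total += suffix(m, flags[m][2])
    return total


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    score: float | None          # percent, None when the denominator is zero
    numerator: int
    denominator: int
    n_paths: int
    n_parameter_vertices: int
    mode: str
    path_kind: str
    parameter_set: str

    @property
    def defined(self) -> bool:
        return self.score is not None


def _parameter_sets(pg: ParameterGraph, which, node: int):
    """(v_rest tuples, label): factor coordinates of every node but ``node``."""
    others = [n for n in range(pg.net.n_nodes) if n != node]
    if isinstance(which, str):
        label = which
        ess = [
            tuple(pool)
            for pool in itertools.product(
                *(pg.factors[n].essential_indices() for n in others)
            )
        ]
        if which == "essential":
            chosen = ess
        elif which == "perturbed":
            chosen = set(ess)
            for v in ess:
                for i, n in enumerate(others):
                    for j in pg.factors[n].neighbors(v[i]):
                        chosen.add(v[:i] + (j,) + v[i + 1:])
            chosen = sorted(chosen)
        else:
            raise ValueError(f"unknown parameter set {which!r}")
    else:
        label = "explicit"
        chosen = [tuple(v) for v in which]
    return chosen, label


def hysteresis_score(
    net_or_pg,
    mode: str = "ascending",
    path_kind: str = "partial",
    parameter_set="essential",
    node: int = 0,
    order: tuple | None = None,
    strict_ends: bool = True,
) -> ScoreReport:
    """Percentage of (path, parameter-vertex) pairs exhibiting hysteresis.

    The parameter set ranges over the factor coordinates of every node
    except the input node; the input node's paths are taken within one
    threshold-order class (the identity class by default).
    """
    if isinstance(net_or_pg, ParameterGraph):
        pg = net_or_pg
    else:
        classes = ["identity" if n == node else "all"
                   for n in range(net_or_pg.n_nodes)]
        pg = build_parameter_graph(net_or_pg, classes=classes)
    succ = signal_dag(pg, node, order)
    fg = pg.factors[node]
    src = fg.minimal_vertex(order)
    tgt = fg.maximal_vertex(order)
    n_paths = count_paths(succ, path_kind, src, tgt)
    rests, label = _parameter_sets(pg, parameter_set, node)
    denominator = n_paths * len(rests)
    if denominator == 0:
        return ScoreReport(None, 0, 0, n_paths, len(rests), mode, path_kind, label)
    numerator = 0
    for rest in rests:
        flags = _vertex_flags(pg, node, list(succ), rest, mode, strict_ends)
        numerator += _count_hysteretic(succ, flags, path_kind, src, tgt)
    return ScoreReport(
        100.0 * numerator / denominator,
        numerator,
        denominator,
        n_paths,
        len(rests),
        mode,
        path_kind,
        label,
    )


def robustness_and_classification(essential: ScoreReport, perturbed: ScoreReport):
    """Robustness = perturbed/essential score; fragile when the ratio ≤ 0.5.

    Returns ``(ratio, label)`` with label in {"fragile", "robust",
    "non-switching"} (the latter when the essential score is 0 or undefined).
    """
    if not essential.defined or essential.score == 0:
        return None, "non-switching"
    ratio = (perturbed.score or 0.0) / essential.score
    return ratio, ("fragile" if ratio <= FRAGILE_CUTOFF else "robust")


def screen(
    networks: Iterable[RegulatoryNetwork],
    mode: str = "ascending",
    path_kind: str = "partial",
    strict_ends: bool = True,
    progress: bool = False,
):
    """Score a collection of networks and rank by descending hysteresis score.

    Returns a pandas DataFrame; per-network failures are recorded in the
    ``error`` column rather than aborting the batch.  Deterministic ranking
    with the canonical network id as tie-break.
    """
    import pandas as pd

    rows = []
    nets = list(networks)
    iterator = nets
    if progress:
        from tqdm import tqdm

        iterator = tqdm(nets)
    for net in iterator:
        nid = canonical_id(net)
        row = {
            "network_id": nid,
            "spec": net.serialize().replace("\n", "; "),
            "n_edges": net.n_edges,
            "consistent": all(
                v != "mixed" for v in node_consistency(net).values()
            ),
        }
        try:
            ess = hysteresis_score(net, mode, path_kind, "essential",
                                   strict_ends=strict_ends)
            per = hysteresis_score(net, mode, path_kind, "perturbed",
                                   strict_ends=strict_ends)
            ratio, label = robustness_and_classification(ess, per)
            row.update(
                hysteresis_score=ess.score,
                perturbed_score=per.score,
                robustness=ratio,
                fragile=label == "fragile",
                essential_numerator=ess.numerator,
                essential_denominator=ess.denominator,
                perturbed_numerator=per.numerator,
                perturbed_denominator=per.denominator,
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - batch mode records failures
            row.update(
                hysteresis_score=None, perturbed_score=None, robustness=None,
                fragile=None, essential_numerator=None,
                essential_denominator=None, perturbed_numerator=None,
                perturbed_denominator=None, error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(
            ["hysteresis_score", "network_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
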