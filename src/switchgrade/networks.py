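"""Annotated regulatory networks: representation, parsing, enumeration, filters.

A regulatory network is a signed digraph on named nodes.  The edge
coefficient ``a[i][j]`` describes the interaction from node ``j`` to node
``i``: ``+1`` activation, ``-1`` repression, ``0`` no edge.  The interaction
algebra is fixed throughout the package: the production rate of a node is
the *sum* of the contributions of its activating in-edges multiplied by the
*factor* contributed by each repressing in-edge.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "RegulatoryNetwork",
    "NetworkParseError",
    "parse_network",
    "enumerate_three_node_networks",
    "is_trivial",
    "node_consistency",
    "canonical_id",
]

SIGNS = (-1, 0, 1)


class NetworkParseError(ValueError):
    """Raised when a network specification cannot be parsed."""


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Signed digraph with the fixed sum-then-multiply interaction algebra.

    Parameters
    ----------
    node_names:
        Ordered node identifiers, indexed ``0..N-1``.
    coeffs:
        ``N x N`` matrix (tuple of tuples) with ``coeffs[i][j]`` the edge
        coefficient from source ``j`` to target ``i``.
    input_node, output_node:
        Distinguished nodes for signal in and read-out.  Default 0 and 2
        (or the last node for networks with fewer than three nodes).
    """

    node_names: tuple[str, ...]
    coeffs: tuple[tuple[int, ...], ...]
    input_node: int = 0
    output_node: int = field(default=-1)

    def __post_init__(self):
        n = len(self.node_names)
        if len(self.coeffs) != n or any(len(row) != n for row in self.coeffs):
            raise ValueError("coefficient matrix shape must match node count")
        for row in self.coeffs:
            for a in row:
                if a not in SIGNS:
                    raise ValueError(f"edge coefficient {a!r} not in {{-1,0,1}}")
        if self.output_node == -1:
            object.__setattr__(self, "output_node", min(2, n - 1))

    # -- basic queries ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def a(self, target: int, source: int) -> int:
        return self.coeffs[target][source]

    def in_edges(self, node: int) -> tuple[tuple[int, int], ...]:
        """In-edges of ``node`` as ``(source, sign)``, sorted by source."""
        return tuple(
            (j, self.coeffs[node][j])
            for j in range(self.n_nodes)
            if self.coeffs[node][j] != 0
        )

    def out_edges(self, node: int) -> tuple[int, ...]:
        """Targets of ``node``'s out-edges, sorted by target index."""
        return tuple(
            i for i in range(self.n_nodes) if self.coeffs[i][node] != 0
        )

    def in_degree(self, node: int) -> int:
        return len(self.in_edges(node))

    def out_degree(self, node: int) -> int:
        return len(self.out_edges(node))

    @property
    def n_edges(self) -> int:
        return sum(1 for row in self.coeffs for a in row if a != 0)

    # -- construction helpers -------------------------------------------
    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Sequence[tuple[int, int, int]],
        names: Sequence[str] | None = None,
        **kw,
    ) -> "RegulatoryNetwork":
        """Build from ``(target, source, sign)`` triples."""
        if names is None:
            names = tuple(f"x{i}" for i in range(n_nodes))
        mat = [[0] * n_nodes for _ in range(n_nodes)]
        for tgt, src, sign in edges:
            mat[tgt][src] = sign
        return cls(tuple(names), tuple(tuple(r) for r in mat), **kw)

    # -- serialization ---------------------------------------------------
    def serialize(self) -> str:
        """Emit the network-spec dialect (round-trips through parsing)."""
        lines = []
        for i, name in enumerate(self.node_names):
            acts = [self.node_names[j] for j, s in self.in_edges(i) if s > 0]
            reps = [self.node_names[j] for j, s in self.in_edges(i) if s < 0]
            rhs = ""
            if acts:
                rhs += "(" + "+".join(acts) + ")"
            rhs += "".join(f"(~{r})" for r in reps)
            lines.append(f"{name} : {rhs}")
        return "\n".join(lines)


_LINE_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*:\s*(.*?)\s*$")
_GROUP_RE = re.compile(r"\(([^()]*)\)")


def parse_network(text: str, input_node: int = 0, output_node: int | None = None) -> RegulatoryNetwork:
    """Parse the one-line-per-node network dialect.

    Each line is ``name : (a+b+...)(~r)(~s)...``; the single un-tilded group
    sums the activating inputs, and each ``(~r)`` group is one multiplicative
    repressor.  Blank lines and ``#`` comments are ignored.
    """
    entries: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise NetworkParseError(f"line {lineno}: malformed node line: {raw!r}")
        entries.append((lineno, m.group(1), m.group(2)))

    names = [name for _, name, _ in entries]
    seen = set()
    for lineno, name, _ in entries:
        if name in seen:
            raise NetworkParseError(f"line {lineno}: node {name!r} defined twice")
        seen.add(name)
    index = {name: i for i, name in enumerate(names)}
    n = len(names)
    mat = [[0] * n for _ in range(n)]

    for lineno, name, rhs in entries:
        i = index[name]
        consumed = _GROUP_RE.sub("", rhs).strip()
        if consumed:
            raise NetworkParseError(
                f"line {lineno}: malformed expression near {consumed!r}"
            )
        n_act_groups = 0
        for group in _GROUP_RE.findall(rhs):
            body = group.strip()
            if not body:
                raise NetworkParseError(f"line {lineno}: empty group")
            if body.startswith("~"):
                src = body[1:].strip()
                if "+" in src:
                    raise NetworkParseError(
                        f"line {lineno}: repressor group (~{src}) must name a single node"
                    )
                if src not in index:
                    raise NetworkParseError(f"line {lineno}: unknown node name {src!r}")
                if mat[i][index[src]] != 0:
                    raise NetworkParseError(
                        f"line {lineno}: duplicate edge from {src!r}"
                    )
                mat[i][index[src]] = -1
            else:
                n_act_groups += 1
                if n_act_groups > 1:
                    raise NetworkParseError(
                        f"line {lineno}: all activators must share one summed group"
                    )
                for src in (s.strip() for s in body.split("+")):
                    if src not in index:
                        raise NetworkParseError(
                            f"line {lineno}: unknown node name {src!r}"
                        )
                    if mat[i][index[src]] != 0:
                        raise NetworkParseError(
                            f"line {lineno}: duplicate edge from {src!r}"
                        )
                    mat[i][index[src]] = 1

    kw = {}
    if output_node is not None:
        kw["output_node"] = output_node
    return RegulatoryNetwork(tuple(names), tuple(tuple(r) for r in mat),
                             input_node=input_node, **kw)


def canonical_id(net: RegulatoryNetwork) -> int:
    """Stable id: base-3 value of the coefficients read row-major, -1<0<+1.

    Specific to this package; unrelated to any ranking-derived numbering.
    """
    v = 0
    for row in net.coeffs:
        for a in row:
            v = 3 * v + (a + 1)
    return v


def is_trivial(net: RegulatoryNetwork) -> bool:
    """A 3-node network is trivial iff |a20*a21| + |a20*a01| + |a21*a10| = 0.

    Equivalently: no path from the input node to the output node, or no path
    from node 1 to the output node, so the circuit cannot switch (or node 1
    cannot matter).
    """
    if net.n_nodes != 3:
        raise ValueError("trivial-network filter is defined for 3-node networks")
    a = net.a
    return abs(a(2, 0) * a(2, 1)) + abs(a(2, 0) * a(0, 1)) + abs(a(2, 1) * a(1, 0)) == 0


def node_consistency(net: RegulatoryNetwork) -> dict[int, str]:
    """Classify each node by the signs of its out-edges.

    Returns ``{node: "activator-only" | "repressor-only" | "mixed" | "no-out"}``.
    A node is *consistent* when it is not mixed.
    """
    result = {}
    for j in range(net.n_nodes):
        signs = {net.coeffs[i][j] for i in net.out_edges(j)}
        if not signs:
            result[j] = "no-out"
        elif signs == {1}:
            result[j] = "activator-only"
        elif signs == {-1}:
            result[j] = "repressor-only"
        else:
            result[j] = "mixed"
    return result


def enumerate_three_node_networks(
    include_trivial: bool = True,
    nine_edge_policy: str = "keep-all",
) -> Iterator[RegulatoryNetwork]:
    """Enumerate 3-node networks in canonical (row-major lexicographic) order.

    ``nine_edge_policy``:
      * ``"keep-all"`` — all 512 nine-edge networks retained;
      * ``"all-activator-only"`` — among nine-edge networks keep only the one
        in which every edge activates;
      * ``"drop-all"`` — drop every nine-edge network.

    With ``include_trivial=True`` and ``"keep-all"`` the count is 3**9 = 19,683.
    The screening set used for ranking is ``include_trivial=False`` with
    ``"all-activator-only"``.
    """
    if nine_edge_policy not in ("keep-all", "all-activator-only", "drop-all"):
        raise ValueError(f"unknown nine_edge_policy {nine_edge_policy!r}")
    names = ("x0", "x1", "x2")
    for flat in itertools.product(SIGNS, repeat=9):
        coeffs = (flat[0:3], flat[3:6], flat[6:9])
        if 0 not in flat:  # nine edges
            if nine_edge_policy == "drop-all":
                continue
            if nine_edge_policy == "all-activator-only" and any(a < 0 for a in flat):
                continue
        net = RegulatoryNetwork(names, coeffs)
        if not include_trivial and is_trivial(net):
            continue
        yield net
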