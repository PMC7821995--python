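"""Directed acyclic graphs over named variables.

The :class:`DAG` is a small immutable structure: a tuple of node names plus a
frozen set of (parent, child) arrows. Mutating operations return new DAGs, so
the greedy structure search can branch cheaply. Acyclicity is enforced on
every construction; CLG legality (no continuous parent of a discrete child)
is enforced by :func:`add_arrow` when variable kinds are supplied, and by
:func:`check_clg_legal` for whole graphs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx

from .exceptions import CycleError, IllegalArrowError, IllegalGraphError
from .variables import VariableSpec


class DAG:
    """Immutable directed acyclic graph.

    Parameters
    ----------
    nodes : iterable of str
    arrows : iterable of (parent, child) pairs
        Must reference declared nodes, contain no self-arrows, no
        duplicates, and admit a topological order.
    """

    __slots__ = ("nodes", "arrows", "_parents", "_children")

    def __init__(self, nodes: Iterable[str], arrows: Iterable[tuple[str, str]] = ()):
        nodes = tuple(dict.fromkeys(nodes))
        arrows_list = list(arrows)
        arrow_set = frozenset(arrows_list)
        if len(arrow_set) != len(arrows_list):
            raise ValueError("duplicate arrows")
        node_set = set(nodes)
        parents: dict[str, set[str]] = {n: set() for n in nodes}
        children: dict[str, set[str]] = {n: set() for n in nodes}
        for p, c in arrow_set:
            if p not in node_set or c not in node_set:
                raise KeyError(f"arrow ({p!r}, {c!r}) references undeclared node")
            if p == c:
                raise CycleError(f"self-arrow on {p!r}")
            parents[c].add(p)
            children[p].add(c)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arrows", arrow_set)
        object.__setattr__(self, "_parents", parents)
        object.__setattr__(self, "_children", children)
        if arrow_set and not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise CycleError("arrow set contains a directed cycle")

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("DAG is immutable")

    # -- queries -----------------------------------------------------------
    def parents(self, node: str) -> set[str]:
        return set(self._parents[node])

    def children(self, node: str) -> set[str]:
        return set(self._children[node])

    def markov_blanket(self, node: str) -> set[str]:
        """Parents, children, and co-parents (other parents of children)."""
        if node not in self._parents:
            raise KeyError(node)
        blanket = set(self._parents[node]) | set(self._children[node])
        for child in self._children[node]:
            blanket |= self._parents[child]
        blanket.discard(node)
        return blanket

    def has_arrow(self, parent: str, child: str) -> bool:
        return (parent, child) in self.arrows

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arrows)
        return g

    # -- edits (return new DAGs) ------------------------------------------
    def with_arrow(self, parent: str, child: str) -> "DAG":
        if (parent, child) in self.arrows:
            raise ValueError(f"arrow {parent!r}->{child!r} already present")
        return DAG(self.nodes, self.arrows | {(parent, child)})

    def without_arrow(self, parent: str, child: str) -> "DAG":
        if (parent, child) not in self.arrows:
            raise KeyError((parent, child))
        return DAG(self.nodes, self.arrows - {(parent, child)})

    def with_reversed(self, parent: str, child: str) -> "DAG":
        if (parent, child) not in self.arrows:
            raise KeyError((parent, child))
        return DAG(self.nodes, (self.arrows - {(parent, child)}) | {(child, parent)})

    def would_cycle(self, parent: str, child: str) -> bool:
        """Would adding parent→child create a directed cycle?"""
        if parent == child:
            return True
        # cycle iff a directed path child ⇝ parent already exists
        seen = {child}
        stack = [child]
        while stack:
            for nxt in self._children[stack.pop()]:
                if nxt == parent:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DAG)
            and set(self.nodes) == set(other.nodes)
            and self.arrows == other.arrows
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.arrows))

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.arrows)} arrows)"

    def format_arrows(self) -> str:
        """One ``parent -> child`` per line, sorted; round-trips via parse_arrows."""
        return "\n".join(f"{p} -> {c}" for p, c in sorted(self.arrows))


def add_arrow(
    dag: DAG, parent: str, child: str, specs: Sequence[VariableSpec] | Mapping[str, VariableSpec]
) -> DAG:
    """Add one arrow, enforcing acyclicity and CLG legality.

    A continuous parent of a discrete child is illegal in a conditional
    linear Gaussian network: discrete nodes may condition only on discrete
    parents.

    Raises
    ------
    KeyError
        Unknown node.
    CycleError
        The arrow would close a directed cycle.
    IllegalArrowError
        Continuous parent of a discrete child.
    """
    if parent not in dag._parents:
        raise KeyError(parent)
    if child not in dag._parents:
        raise KeyError(child)
    spec_map = specs if isinstance(specs, Mapping) else {s.name: s for s in specs}
    if spec_map[parent].is_continuous and spec_map[child].is_discrete:
        raise IllegalArrowError(
            f"continuous {parent!r} cannot be a parent of discrete {child!r}"
        )
    if dag.would_cycle(parent, child):
        raise CycleError(f"arrow {parent!r}->{child!r} would create a cycle")
    return dag.with_arrow(parent, child)


def check_clg_legal(dag: DAG, specs: Mapping[str, VariableSpec]) -> None:
    """Raise IllegalGraphError unless every arrow is CLG-legal."""
    for node in dag.nodes:
        if node not in specs:
            raise IllegalGraphError(f"no variable declared for node {node!r}")
    for p, c in dag.arrows:
        if specs[p].is_continuous and specs[c].is_discrete:
            raise IllegalGraphError(
                f"continuous {p!r} is a parent of discrete {c!r}"
            )


def is_clg_legal(dag: DAG, specs: Mapping[str, VariableSpec]) -> bool:
    try:
        check_clg_legal(dag, specs)
    except IllegalGraphError:
        return False
    return True


def structural_hamming_distance(a: DAG, b: DAG) -> int:
    """Edge-edit distance between two DAGs on the same node set.

    Counts 1 for each edge present in only one graph (as an undirected
    adjacency) and 1 for each shared edge oriented differently.
    """
    if set(a.nodes) != set(b.nodes):
        raise ValueError("DAGs must share a node set")
    skel_a = {frozenset(e) for e in a.arrows}
    skel_b = {frozenset(e) for e in b.arrows}
    dist = len(skel_a ^ skel_b)
    for e in skel_a & skel_b:
        u, v = tuple(e)
        if ((u, v) in a.arrows) != ((u, v) in b.arrows):
            dist += 1
    return dist


def parse_arrows(text: str, nodes: Iterable[str]) -> DAG:
    """Parse the ``parent -> child`` per-line text format back into a DAG."""
    arrows = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise ValueError(f"line {i}: expected 'parent -> child'")
        parent, child = (part.strip() for part in line.split("->", 1))
        arrows.append((parent, child))
    return DAG(nodes, arrows)
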