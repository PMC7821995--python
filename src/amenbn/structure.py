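"""Hybrid structure learning over CLG-legal DAGs.

The constraint phase (:func:`mmpc`, :func:`mmpc_skeleton`) discovers each
node's candidate parents-and-children set with the max-min heuristic and
builds an undirected skeleton by symmetry correction. The score phase
(:func:`hill_climb`) greedily maximizes the decomposable CLG-BIC score over
add/delete/reverse single-arrow moves. :func:`mmhc` chains the two;
:func:`rsmax2` is the generalization hook accepting any restrict/maximize
pair (the other constraint algorithms of the bnlearn family — GS, IAMB and
variants, SI-HITON-PC, TABU — are deliberately not implemented and would
plug in there).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from ._lik import (
    combine_codes,
    gaussian_loglik_params,
    grouped_gaussian_fit,
    multinomial_loglik,
)
from .citests import ALPHA_DEFAULT, ci_test
from .exceptions import (
    DegenerateError,
    IllegalGraphError,
    InsufficientDataError,
)
from .graph import DAG, check_clg_legal
from .variables import DataTable


@dataclass(frozen=True)
class Skeleton:
    """Undirected candidate structure: nodes plus unordered edges."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for edge in self.edges:
            if len(edge) != 2:
                raise ValueError(f"self-edge or malformed edge {set(edge)}")
            if not edge <= node_set:
                raise ValueError(f"edge {set(edge)} references undeclared node")

    def allows(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


def complete_skeleton(nodes: Iterable[str]) -> Skeleton:
    nodes = tuple(nodes)
    return Skeleton(
        nodes, frozenset(frozenset(p) for p in itertools.combinations(nodes, 2))
    )


class TestDispatcher:
    """Routes, caches and counts conditional-independence tests.

    Degenerate or data-starved tests are reported as independence (p = 1)
    so the learning loops stay total. ``n_tests`` counts actual test
    computations (cache hits are not re-counted).
    """

    def __init__(self, data: DataTable):
        self.data = data
        self._cache: dict[tuple, float] = {}
        self.n_tests = 0

    def p_value(self, x: str, y: str, cond: Iterable[str] = ()) -> float:
        cond_key = frozenset(cond)
        key = (frozenset((x, y)), cond_key)
        if key in self._cache:
            return self._cache[key]
        # canonical orientation so the cache key is symmetric in (x, y)
        a, b = sorted(
            (x, y), key=lambda v: (self.data.specs[v].is_discrete, v)
        )
        try:
            p = ci_test(self.data, a, b, tuple(sorted(cond_key))).p_value
        except (DegenerateError, InsufficientDataError):
            p = 1.0
        self.n_tests += 1
        self._cache[key] = p
        return p


# ---------------------------------------------------------------------------
# MMPC
# ---------------------------------------------------------------------------

def _subsets(pool: Iterable[str], containing: str | None = None):
    pool = sorted(pool)
    for size in range(len(pool) + 1):
        for sub in itertools.combinations(pool, size):
            if containing is None or containing in sub:
                yield sub


def mmpc(
    data: DataTable,
    target: str,
    alpha: float = ALPHA_DEFAULT,
    dispatcher: TestDispatcher | None = None,
) -> set[str]:
    """Max-min parents-and-children discovery for one target.

    Forward phase: repeatedly admit the candidate whose *worst-case*
    association with the target (the maximum p-value over subsets of the
    current candidate set) is smallest, provided it is significant at
    ``alpha``; candidates whose worst-case association loses significance
    are discarded permanently. Backward phase: remove any admitted variable
    that is independent of the target given some subset of the others.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if target not in data.specs:
        raise KeyError(target)
    disp = dispatcher or TestDispatcher(data)
    others = [n for n in data.names if n != target]
    if not others:
        return set()
    cpc: list[str] = []
    maxp = {x: 0.0 for x in others}
    remaining = set(others)
    last_added: str | None = None
    first_pass = True
    while remaining:
        for x in sorted(remaining):
            subsets = (
                _subsets(cpc) if first_pass else _subsets(cpc, containing=last_added)
            )
            for sub in subsets:
                p = disp.p_value(target, x, sub)
                if p > maxp[x]:
                    maxp[x] = p
                    if p > alpha:
                        break
            if maxp[x] > alpha:
                remaining.discard(x)
        if not remaining:
            break
        best = min(remaining, key=lambda v: (maxp[v], v))
        cpc.append(best)
        remaining.discard(best)
        last_added = best
        first_pass = False
    # backward phase
    for x in list(cpc):
        rest = [c for c in cpc if c != x]
        for sub in _subsets(rest):
            if disp.p_value(target, x, sub) > alpha:
                cpc.remove(x)
                break
    return set(cpc)


def mmpc_skeleton(
    data: DataTable,
    alpha: float = ALPHA_DEFAULT,
    dispatcher: TestDispatcher | None = None,
) -> Skeleton:
    """Skeleton from per-node MMPC runs with AND-symmetry correction."""
    if len(data.names) < 2:
        raise ValueError("need at least two variables")
    disp = dispatcher or TestDispatcher(data)
    neighbour = {n: mmpc(data, n, alpha, disp) for n in data.names}
    edges = set()
    for x in data.names:
        for y in neighbour[x]:
            if x in neighbour[y]:
                edges.add(frozenset((x, y)))
    return Skeleton(tuple(data.names), frozenset(edges))


# ---------------------------------------------------------------------------
# CLG-BIC scoring
# ---------------------------------------------------------------------------

class ScoreCache:
    """Memo of local scores keyed by (node, frozen parent set)."""

    def __init__(self, data: DataTable):
        self.data = data
        self._scores: dict[tuple[str, frozenset], float] = {}
        self._order = [v.name for v in data.variables]
        self._log_n = math.log(data.n) if data.n else 0.0

    def local_score(self, node: str, parents: Iterable[str]) -> float:
        parents = frozenset(parents)
        key = (node, parents)
        if key in self._scores:
            return self._scores[key]
        data, specs = self.data, self.data.specs
        spec = specs[node]
        disc_pa = [n for n in self._order if n in parents and specs[n].is_discrete]
        cont_pa = [n for n in self._order if n in parents and specs[n].is_continuous]
        if spec.is_discrete and cont_pa:
            raise IllegalGraphError(
                f"continuous parents {cont_pa} of discrete node {node!r}"
            )
        groups, n_groups = combine_codes(
            [data.codes(p) for p in disc_pa],
            [specs[p].n_levels for p in disc_pa],
            data.n,
        )
        if spec.is_discrete:
            ll, k = multinomial_loglik(
                data.codes(node), spec.n_levels, groups, n_groups
            )
        else:
            X = (
                np.column_stack([data.column(c) for c in cont_pa])
                if cont_pa
                else None
            )
            p = len(cont_pa)
            fits = grouped_gaussian_fit(
                data.column(node).astype(float), X, groups, n_groups,
                tuple(range(p - 1, -1, -1)),
            )
            ll, k = gaussian_loglik_params(fits)
        score = ll - 0.5 * k * self._log_n
        self._scores[key] = score
        return score


def clg_bic_score(dag: DAG, data: DataTable, cache: ScoreCache | None = None) -> float:
    """Decomposable BIC of a CLG-legal DAG: Σ [ℓ_local − (k_local/2)·ln n].

    Higher is better. Discrete nodes use the per-configuration multinomial
    MLE with the full declared parameter count; continuous nodes use the
    per-configuration Gaussian regressions, counting (retained slopes +
    intercept + variance) per non-empty configuration.
    """
    check_clg_legal(dag, data.specs)
    if data.n < 1:
        raise InsufficientDataError("cannot score an empty dataset")
    cache = cache or ScoreCache(data)
    return sum(cache.local_score(node, dag.parents(node)) for node in dag.nodes)


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------

_SCORE_EPS = 1e-9


def hill_climb(
    data: DataTable,
    restrict: Skeleton | None = None,
    max_iter: int = 200,
    seed: int = 0,
    start: DAG | None = None,
    cache: ScoreCache | None = None,
) -> DAG:
    """BIC-scored greedy search over add/delete/reverse single-arrow moves.

    Additions are limited to skeleton edges when ``restrict`` is given;
    CLG-illegal and cycle-forming moves are never proposed. Among
    equal-score improving moves the lexicographically smallest
    (operation, parent, child) wins, which makes the search fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic learners but is not consumed.
    """
    specs = data.specs
    nodes = list(data.names)
    cache = cache or ScoreCache(data)
    dag = start if start is not None else DAG(nodes)
    local = {n: cache.local_score(n, dag.parents(n)) for n in nodes}

    def legal_arrow(p: str, c: str) -> bool:
        return not (specs[p].is_continuous and specs[c].is_discrete)

    for _ in range(max_iter):
        best: tuple | None = None  # (delta, op, parent, child)
        for p, c in itertools.permutations(nodes, 2):
            if dag.has_arrow(p, c):
                delta_del = cache.local_score(c, dag.parents(c) - {p}) - local[c]
                cand = (delta_del, "delete", p, c)
                if delta_del > _SCORE_EPS and (best is None or _better(cand, best)):
                    best = cand
                if legal_arrow(c, p) and not dag.without_arrow(p, c).would_cycle(c, p):
                    delta_rev = (
                        cache.local_score(p, dag.parents(p) | {c})
                        - local[p]
                        + cache.local_score(c, dag.parents(c) - {p})
                        - local[c]
                    )
                    cand = (delta_rev, "reverse", p, c)
                    if delta_rev > _SCORE_EPS and (best is None or _better(cand, best)):
                        best = cand
            else:
                if not legal_arrow(p, c):
                    continue
                if restrict is not None and not restrict.allows(p, c):
                    continue
                if dag.would_cycle(p, c):
                    continue
                delta_add = cache.local_score(c, dag.parents(c) | {p}) - local[c]
                cand = (delta_add, "add", p, c)
                if delta_add > _SCORE_EPS and (best is None or _better(cand, best)):
                    best = cand
        if best is None:
            break
        _, op, p, c = best
        if op == "add":
            dag = dag.with_arrow(p, c)
        elif op == "delete":
            dag = dag.without_arrow(p, c)
        else:
            dag = dag.with_reversed(p, c)
        local[c] = cache.local_score(c, dag.parents(c))
        local[p] = cache.local_score(p, dag.parents(p))
    check_clg_legal(dag, specs)
    return dag


def _better(cand: tuple, best: tuple) -> bool:
    """Higher delta wins; ties break lexicographically on (op, parent, child)."""
    if cand[0] > best[0] + _SCORE_EPS:
        return True
    if cand[0] < best[0] - _SCORE_EPS:
        return False
    return cand[1:] < best[1:]


# ---------------------------------------------------------------------------
# Hybrid combiners
# ---------------------------------------------------------------------------

@dataclass
class LearnResult:
    """Output of a hybrid learner: the DAG plus learning diagnostics."""

    dag: DAG
    skeleton: Skeleton
    n_ci_tests: int
    algorithm: str
    score: float = field(default=float("nan"))


def mmhc(data: DataTable, alpha: float = ALPHA_DEFAULT, seed: int = 0) -> LearnResult:
    """Max-min hill climbing: HC restricted to the MMPC skeleton."""
    disp = TestDispatcher(data)
    skeleton = mmpc_skeleton(data, alpha, disp)
    cache = ScoreCache(data)
    dag = hill_climb(data, restrict=skeleton, seed=seed, cache=cache)
    return LearnResult(
        dag, skeleton, disp.n_tests, "mmhc", clg_bic_score(dag, data, cache)
    )


def rsmax2(
    data: DataTable,
    restrict_fn: Callable[..., Skeleton] | None = None,
    maximize_fn: Callable[..., DAG] | None = None,
    alpha: float = ALPHA_DEFAULT,
    seed: int = 0,
) -> LearnResult:
    """Two-phase restrict/maximize learner, parameterized by its phases.

    With the bundled defaults (``mmpc_skeleton`` + ``hill_climb``) this is
    definitionally identical to :func:`mmhc`. Alternative restrict or
    search algorithms plug in via ``restrict_fn(data, alpha, dispatcher)``
    and ``maximize_fn(data, restrict, seed)``.
    """
    restrict_fn = restrict_fn or mmpc_skeleton
    maximize_fn = maximize_fn or hill_climb
    disp = TestDispatcher(data)
    try:
        skeleton = restrict_fn(data, alpha, disp)
    except TypeError:
        skeleton = restrict_fn(data, alpha)
    dag = maximize_fn(data, skeleton, seed=seed)
    check_clg_legal(dag, data.specs)
    return LearnResult(
        dag, skeleton, disp.n_tests, "rsmax2", clg_bic_score(dag, data)
    )
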