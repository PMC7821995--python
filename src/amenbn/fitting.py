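"""Maximum-likelihood parameterization of a CLG network on a fixed DAG.

A conditional linear Gaussian network attaches to each discrete node a
conditional probability table over its (necessarily discrete) parents, and
to each continuous node one ordinary-least-squares regression on its
continuous parents *per joint configuration of its discrete parents*:

    X | pa_D = d, pa_C = x  ~  N(β₀(d) + β(d)·x, σ²(d))

The per-configuration regressions are the practical artifact: for the AMEn
target with discrete parents category × animal × ingredient they are the
twelve prediction equations a nutritionist would actually use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._lik import combine_codes, grouped_gaussian_fit
from .exceptions import (
    IllegalGraphError,
    MissingCovariateError,
    NoEquationError,
    NotContinuousError,
)
from .graph import DAG, check_clg_legal
from .variables import DataTable, DiscreteConfig, VariableSpec

#: priority used to order equation tables; remaining parents follow in
#: declaration order
CONFIG_ORDER_PRIORITY = ("category", "animal", "ingredient")


@dataclass(frozen=True)
class LinearEquation:
    """One per-configuration linear prediction equation.

    ``coefficients`` maps continuous covariates to slopes; ``dropped`` lists
    covariates that were not estimable for this configuration (rendered as
    "-" in tables). ``n_config == 0`` flags a configuration never observed
    in the training data, for which the intercept falls back to the grand
    mean of the target and every covariate is dropped.
    """

    config: DiscreteConfig
    intercept: float
    coefficients: dict[str, float]
    residual_sd: float
    n_config: int
    dropped: frozenset[str] = frozenset()
    intercept_se: float = float("nan")
    coef_se: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dropped & set(self.coefficients):
            raise ValueError("a covariate cannot be both dropped and retained")
        if self.n_config < 0:
            raise ValueError("n_config must be >= 0")

    def predict(self, record: Mapping[str, float]) -> float:
        """Evaluate intercept + Σ coefficient·covariate on one record."""
        value = self.intercept
        for cov, coef in self.coefficients.items():
            if cov not in record:
                raise MissingCovariateError(f"record lacks covariate {cov!r}")
            value += coef * float(record[cov])
        return value


def render_equation(
    eq: LinearEquation,
    target: str,
    display: Mapping[str, str] | None = None,
    precision: int = 2,
) -> str:
    """Human-readable form, e.g. ``AMEn = 3658.16 - 2.41 CP + 16.76 CF``."""
    display = display or {}
    parts = [f"{display.get(target, target)} = {eq.intercept:.{precision}f}"]
    for cov, coef in eq.coefficients.items():
        sign = "-" if coef < 0 else "+"
        parts.append(f"{sign} {abs(coef):.{precision}f} {display.get(cov, cov)}")
    return " ".join(parts)


class CLGNetwork:
    """A DAG plus its local distributions.

    ``discrete_locals[node]`` is a CPT: dict mapping each joint parent-level
    tuple (parents in ``cpt_parents[node]`` order) to a probability vector
    over the node's declared levels. ``continuous_locals[node]`` is the list
    of per-configuration :class:`LinearEquation`. Together they encode the
    usual factorization P(X₁..Xₚ) = Π P(Xᵢ | pa(Xᵢ)).
    """

    def __init__(
        self,
        variables: Sequence[VariableSpec],
        dag: DAG,
        discrete_locals: Mapping[str, Mapping[tuple, np.ndarray]],
        continuous_locals: Mapping[str, list[LinearEquation]],
        cpt_parents: Mapping[str, tuple[str, ...]] | None = None,
    ):
        self.variables = tuple(variables)
        self.specs = {v.name: v for v in variables}
        check_clg_legal(dag, self.specs)
        self.dag = dag
        self.discrete_locals = {k: dict(v) for k, v in discrete_locals.items()}
        self.continuous_locals = {k: list(v) for k, v in continuous_locals.items()}
        self.cpt_parents = dict(cpt_parents or {})
        for node in dag.nodes:
            spec = self.specs[node]
            if spec.is_discrete:
                if node not in self.discrete_locals:
                    raise IllegalGraphError(f"no CPT for discrete node {node!r}")
                for cfg, probs in self.discrete_locals[node].items():
                    probs = np.asarray(probs, dtype=float)
                    if probs.shape != (spec.n_levels,):
                        raise ValueError(f"CPT row shape mismatch for {node!r}")
                    if abs(float(probs.sum()) - 1.0) > 1e-9:
                        raise ValueError(f"CPT row for {node!r} {cfg} does not sum to 1")
                    self.discrete_locals[node][cfg] = probs
            else:
                if node not in self.continuous_locals:
                    raise IllegalGraphError(f"no local model for {node!r}")

    def equations(self, target: str) -> list[LinearEquation]:
        return extract_equations(self, target)

    def predict(self, data: DataTable | Mapping, target: str) -> np.ndarray | float:
        """Predict the target for a DataTable (vector) or one record (scalar)."""
        eqs = self.continuous_locals[target]
        if isinstance(data, DataTable):
            records = (row._asdict() for row in data.df.itertuples(index=False))
            return np.array([predict_target(eqs, rec) for rec in records])
        return predict_target(eqs, data)


def fit_clg(dag: DAG, data: DataTable) -> CLGNetwork:
    """Maximum-likelihood CLG parameterization of ``dag`` from ``data``.

    Discrete nodes get empirical conditional frequencies (uniform rows for
    unobserved parent configurations); continuous nodes get one OLS fit per
    discrete-parent configuration, with rank-deficient or undersized
    configurations repaired by dropping covariates in reverse declaration
    order. Residual variance uses the MLE denominator ``n_config`` for
    consistency with the BIC log-likelihood.
    """
    specs = data.specs
    check_clg_legal(dag, specs)
    for node in dag.nodes:
        if node not in specs:
            raise IllegalGraphError(f"data lacks variable {node!r}")
    order = [v.name for v in data.variables]
    discrete_locals: dict[str, dict[tuple, np.ndarray]] = {}
    continuous_locals: dict[str, list[LinearEquation]] = {}
    cpt_parents: dict[str, tuple[str, ...]] = {}

    for node in dag.nodes:
        spec = specs[node]
        parents = dag.parents(node)
        disc_pa = [n for n in order if n in parents and specs[n].is_discrete]
        cont_pa = [n for n in order if n in parents and specs[n].is_continuous]
        pa_levels = [specs[p].levels for p in disc_pa]
        sizes = [len(lv) for lv in pa_levels]
        groups, n_groups = combine_codes(
            [data.codes(p) for p in disc_pa], sizes, data.n
        )
        if spec.is_discrete:
            codes = data.codes(node)
            L = spec.n_levels
            counts = np.bincount(groups * L + codes, minlength=n_groups * L)
            counts = counts.reshape(n_groups, L).astype(float)
            cpt: dict[tuple, np.ndarray] = {}
            for g, cfg in enumerate(itertools.product(*pa_levels) if disc_pa else [()]):
                tot = counts[g].sum()
                cpt[cfg] = counts[g] / tot if tot > 0 else np.full(L, 1.0 / L)
            discrete_locals[node] = cpt
            cpt_parents[node] = tuple(disc_pa)
        else:
            y = data.column(node).astype(float)
            X = (
                np.column_stack([data.column(c) for c in cont_pa])
                if cont_pa
                else None
            )
            p = len(cont_pa)
            fits = grouped_gaussian_fit(
                y, X, groups, n_groups, tuple(range(p - 1, -1, -1))
            )
            grand_mean = float(np.mean(y)) if data.n else 0.0
            grand_sd = float(np.std(y)) if data.n else 0.0
            eqs = []
            configs = itertools.product(*pa_levels) if disc_pa else [()]
            for fit, cfg in zip(fits, configs):
                config = DiscreteConfig.from_mapping(dict(zip(disc_pa, cfg)))
                if fit.n == 0:
                    eqs.append(
                        LinearEquation(
                            config, grand_mean, {}, grand_sd, 0,
                            dropped=frozenset(cont_pa),
                        )
                    )
                    continue
                coeffs = {cont_pa[j]: float(b) for j, b in zip(fit.kept, fit.beta[1:])}
                ses = {cont_pa[j]: float(s) for j, s in zip(fit.kept, fit.se[1:])}
                eqs.append(
                    LinearEquation(
                        config,
                        float(fit.beta[0]),
                        coeffs,
                        float(np.sqrt(fit.sigma2)),
                        fit.n,
                        dropped=frozenset(cont_pa[j] for j in fit.dropped),
                        intercept_se=float(fit.se[0]) if fit.se.size else float("nan"),
                        coef_se=ses,
                    )
                )
            continuous_locals[node] = eqs
    return CLGNetwork(data.variables, dag, discrete_locals, continuous_locals, cpt_parents)


def extract_equations(network: CLGNetwork, target: str) -> list[LinearEquation]:
    """The per-configuration equations for ``target``, canonically ordered.

    Ordering: configurations sort by the levels of the discrete parents
    taken in :data:`CONFIG_ORDER_PRIORITY` order (category, animal,
    ingredient) with any remaining parents in declaration order, levels in
    declared order.
    """
    if not network.specs[target].is_continuous:
        raise NotContinuousError(f"{target!r} is not continuous")
    eqs = network.continuous_locals[target]
    parents = sorted(
        {name for eq in eqs for name, _ in eq.config.assignment},
        key=lambda n: (
            CONFIG_ORDER_PRIORITY.index(n)
            if n in CONFIG_ORDER_PRIORITY
            else len(CONFIG_ORDER_PRIORITY),
            [v.name for v in network.variables].index(n),
        ),
    )

    def key(eq: LinearEquation):
        cfg = eq.config.as_dict()
        return tuple(network.specs[p].levels.index(cfg[p]) for p in parents)

    return sorted(eqs, key=key)


def equations_frame(network: CLGNetwork, target: str) -> "pd.DataFrame":
    """Equation table as a DataFrame (full precision; dropped cells NaN).

    Columns: the discrete parents (category/animal/ingredient order when
    present), intercept, one column per continuous parent, residual_sd and
    n_config — the familiar published-table layout.
    """
    import pandas as pd

    eqs = extract_equations(network, target)
    order = [v.name for v in network.variables]
    parents = network.dag.parents(target)
    cont_pa = [n for n in order if n in parents and network.specs[n].is_continuous]
    disc_pa = sorted(
        (n for n in parents if network.specs[n].is_discrete),
        key=lambda n: (
            CONFIG_ORDER_PRIORITY.index(n)
            if n in CONFIG_ORDER_PRIORITY
            else len(CONFIG_ORDER_PRIORITY),
            order.index(n),
        ),
    )
    rows = []
    for eq in eqs:
        cfg = eq.config.as_dict()
        row: dict = {p: cfg.get(p, "") for p in disc_pa}
        row["intercept"] = eq.intercept
        for cov in cont_pa:
            row[cov] = eq.coefficients.get(cov, float("nan"))
        row["residual_sd"] = eq.residual_sd
        row["n_config"] = eq.n_config
        rows.append(row)
    return pd.DataFrame(rows)


def format_equations_table(network: CLGNetwork, target: str, precision: int = 2) -> str:
    """Fixed-precision text rendering of the equation table ("-" = dropped)."""
    frame = equations_frame(network, target).copy()
    for col in frame.columns:
        if frame[col].dtype.kind == "f":
            frame[col] = frame[col].map(
                lambda v: "-" if np.isnan(v) else f"{v:.{precision}f}"
            )
    return frame.to_string(index=False)


def predict_target(equations: Iterable[LinearEquation], record: Mapping) -> float:
    """Evaluate the equation matching the record's discrete configuration."""
    matches = [eq for eq in equations if eq.config.matches(record)]
    if len(matches) != 1:
        raise NoEquationError(
            f"{len(matches)} equations match record configuration "
            f"{ {k: v for k, v in record.items() if isinstance(v, str)} }"
        )
    return matches[0].predict(record)
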