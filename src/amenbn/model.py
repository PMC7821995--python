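"""Model/Results surface tying the pipeline together.

:class:`CLGModel` holds a validated dataset (and optionally a fixed DAG);
``fit()`` learns the structure if asked, parameterizes the conditional
linear Gaussian network by maximum likelihood, and returns a
:class:`CLGResults` carrying the network, the learning diagnostics, the
per-configuration prediction equations, prediction, validation and
simulation.

    >>> model = CLGModel.from_dataframe(df, discrete={"category": [...]})
    >>> res = model.fit(structure="mmhc", alpha=0.05, seed=1)
    >>> print(res.summary())
    >>> res.predict(new_records, target="amen")
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .citests import ALPHA_DEFAULT
from .fitting import (
    CLGNetwork,
    LinearEquation,
    extract_equations,
    fit_clg,
    format_equations_table,
)
from .graph import DAG
from .reference import DISPLAY_NAMES
from .structure import LearnResult, Skeleton, hill_climb, mmhc, rsmax2
from .validation import MetricsReport, compute_metrics
from .variables import DataTable, VariableSpec


class CLGModel:
    """Conditional linear Gaussian Bayesian network model for mixed data.

    Parameters
    ----------
    data : DataTable
        Training data with declared variable kinds and levels.
    dag : DAG, optional
        A fixed structure. When omitted, ``fit`` must be asked to learn one
        (``structure="mmhc" | "hc" | "rsmax2"``).
    """

    def __init__(self, data: DataTable, dag: DAG | None = None):
        self.data = data
        self.dag = dag

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        discrete: Mapping[str, Sequence[str]] | None = None,
        units: Mapping[str, str] | None = None,
        dag: DAG | None = None,
    ) -> "CLGModel":
        """Build from a DataFrame; ``discrete`` maps column → ordered levels.

        Columns not named in ``discrete`` are treated as continuous.
        """
        discrete = discrete or {}
        units = units or {}
        variables = [
            VariableSpec(c, "discrete", tuple(discrete[c]), units.get(c, ""))
            if c in discrete
            else VariableSpec(c, "continuous", units=units.get(c, ""))
            for c in df.columns
        ]
        return cls(DataTable(variables, df), dag=dag)

    def fit(
        self,
        structure: str | None = None,
        alpha: float = ALPHA_DEFAULT,
        seed: int = 0,
        restrict: Skeleton | None = None,
    ) -> "CLGResults":
        """Learn the structure if requested, then fit the CLG parameters.

        ``structure`` is one of None (use the fixed DAG), ``"mmhc"``,
        ``"hc"`` (unrestricted hill climbing, or restricted to ``restrict``)
        or ``"rsmax2"`` (bundled MMPC + hill-climbing plugins).
        """
        learn: LearnResult | None = None
        if structure is None:
            if self.dag is None:
                raise ValueError("no DAG fixed; pass structure= to learn one")
            dag = self.dag
        elif structure == "mmhc":
            learn = mmhc(self.data, alpha=alpha, seed=seed)
            dag = learn.dag
        elif structure == "rsmax2":
            learn = rsmax2(self.data, alpha=alpha, seed=seed)
            dag = learn.dag
        elif structure == "hc":
            dag = hill_climb(self.data, restrict=restrict, seed=seed)
        else:
            raise ValueError(f"unknown structure learner {structure!r}")
        network = fit_clg(dag, self.data)
        return CLGResults(self, network, learn, structure, alpha, seed)


class CLGResults:
    """Fitted CLG network plus diagnostics and downstream operations."""

    def __init__(
        self,
        model: CLGModel,
        network: CLGNetwork,
        learn: LearnResult | None,
        structure: str | None,
        alpha: float,
        seed: int,
    ):
        self.model = model
        self.network = network
        self.dag = network.dag
        self.learn = learn
        self.structure = structure
        self.alpha = alpha
        self.seed = seed
        self.n_ci_tests = learn.n_ci_tests if learn is not None else 0

    # -- downstream operations --------------------------------------------
    def equations(self, target: str) -> list[LinearEquation]:
        return extract_equations(self.network, target)

    def predict(self, data: DataTable | pd.DataFrame | Mapping, target: str):
        if isinstance(data, pd.DataFrame):
            eqs = self.network.continuous_locals[target]
            from .fitting import predict_target

            return np.array(
                [predict_target(eqs, row._asdict()) for row in data.itertuples(index=False)]
            )
        return self.network.predict(data, target)

    def validate(self, data: DataTable, target: str) -> MetricsReport:
        """Predict the target on held-out data and score against observations."""
        predicted = self.network.predict(data, target)
        return compute_metrics(predicted, data.column(target).astype(float))

    def simulate(self, n: int, seed: int = 0) -> DataTable:
        """Forward-sample n records from the fitted network (no truncation)."""
        from .simulate import sample_network

        return sample_network(self.network, n, seed=seed)

    def factorization(self) -> str:
        """The joint-distribution factorization implied by the DAG."""
        parts = []
        for node in self.dag.topological_order():
            parents = sorted(self.dag.parents(node))
            parts.append(
                f"P({node})" if not parents else f"P({node} | {', '.join(parents)})"
            )
        joint = ", ".join(self.dag.nodes)
        return f"P({joint}) = " + " · ".join(parts)

    def summary(self, target: str | None = None) -> str:
        """Text summary: structure, diagnostics, and the equation table."""
        if target is None:
            candidates = [
                n for n in self.dag.nodes
                if self.network.specs[n].is_continuous and self.dag.parents(n)
            ]
            # default to the most-conditioned continuous node (the target
            # of a prediction network)
            target = (
                max(candidates, key=lambda n: len(self.dag.parents(n)))
                if candidates
                else None
            )
        lines = [
            "Conditional linear Gaussian Bayesian network",
            "=" * 60,
            f"n obs:          {self.model.data.n}",
            f"nodes:          {len(self.dag.nodes)}",
            f"arrows:         {len(self.dag.arrows)}",
            f"structure:      {self.structure or 'fixed DAG'}",
        ]
        if self.learn is not None:
            lines.append(f"CI tests:       {self.n_ci_tests}")
            lines.append(f"alpha:          {self.alpha}")
            lines.append(f"BIC score:      {self.learn.score:.2f}")
        lines.append("")
        lines.append(self.factorization())
        if target is not None:
            mb = sorted(self.dag.markov_blanket(target))
            lines += [
                "",
                f"Markov blanket of {target}: {{{', '.join(mb)}}}",
                "",
                f"Prediction equations for {target}:",
                format_equations_table(self.network, target),
            ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CLGResults: {len(self.dag.nodes)} nodes, "
            f"{len(self.dag.arrows)} arrows, structure={self.structure!r}>"
        )
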