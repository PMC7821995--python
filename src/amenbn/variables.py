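"""Variable declarations and the mixed-type data table.

A :class:`VariableSpec` declares one variable as either discrete (with an
ordered, closed set of level labels) or continuous (with free-text units).
A :class:`DataTable` couples a pandas DataFrame with its variable
declarations and validates every cell against them, so that everything
downstream — independence tests, structure search, CLG fitting — can trust
the types without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single variable.

    Parameters
    ----------
    name : str
        Canonical identifier (e.g. ``"amen"``, ``"cp"``).
    kind : {"discrete", "continuous"}
    levels : tuple of str, optional
        Ordered level labels; required for discrete, forbidden for
        continuous variables.
    units : str, optional
        Free text, e.g. ``"kcal/kg"`` or ``"%"``.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.kind == "discrete":
            if not self.levels:
                raise ValueError(f"discrete variable {self.name!r} needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"duplicate levels for {self.name!r}")
        elif self.levels:
            raise ValueError(f"continuous variable {self.name!r} cannot have levels")

    @property
    def is_discrete(self) -> bool:
        return self.kind == "discrete"

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class DataTable:
    """Validated mixed-type dataset.

    Wraps a DataFrame whose columns are exactly the declared variables.
    Discrete columns must take values in their declared levels; continuous
    columns must be finite floats.
    """

    def __init__(self, variables: Sequence[VariableSpec], df: pd.DataFrame):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise SchemaError(f"columns missing from data: {missing}")
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        self.specs: dict[str, VariableSpec] = {v.name: v for v in variables}
        df = df.loc[:, names].reset_index(drop=True)
        for spec in variables:
            col = df[spec.name]
            if spec.is_discrete:
                bad = ~col.isin(spec.levels)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise SchemaError(
                        f"variable {spec.name!r}, row {row}: value "
                        f"{col.iloc[row]!r} not in levels {list(spec.levels)}"
                    )
                df[spec.name] = col.astype(str)
            else:
                vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
                if len(vals) and not np.all(np.isfinite(vals)):
                    row = int(np.flatnonzero(~np.isfinite(vals))[0])
                    raise SchemaError(
                        f"variable {spec.name!r}, row {row}: non-finite value"
                    )
                df[spec.name] = vals
        self.df: pd.DataFrame = df
        self._column_cache: dict[str, np.ndarray] = {}
        self._code_cache: dict[str, np.ndarray] = {}

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def kind(self, name: str) -> str:
        return self.specs[name].kind

    def discrete_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.is_discrete)

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.is_continuous)

    def column(self, name: str) -> np.ndarray:
        if name not in self._column_cache:
            self._column_cache[name] = self.df[name].to_numpy()
        return self._column_cache[name]

    def codes(self, name: str) -> np.ndarray:
        """Integer level codes of a discrete column, in declared level order."""
        spec = self.specs[name]
        if not spec.is_discrete:
            raise ValueError(f"{name!r} is continuous")
        if name not in self._code_cache:
            cat = pd.Categorical(self.df[name], categories=list(spec.levels))
            self._code_cache[name] = np.asarray(cat.codes, dtype=np.int64)
        return self._code_cache[name]

    def subset(self, mask_or_index) -> "DataTable":
        return DataTable(self.variables, self.df.iloc[mask_or_index])

    def select(self, names: Iterable[str]) -> "DataTable":
        names = list(names)
        return DataTable([self.specs[n] for n in names], self.df[names])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kinds = {"discrete": 0, "continuous": 0}
        for v in self.variables:
            kinds[v.kind] += 1
        return (
            f"DataTable(n={self.n}, continuous={kinds['continuous']}, "
            f"discrete={kinds['discrete']})"
        )


@dataclass(frozen=True)
class DiscreteConfig:
    """One joint assignment of levels to a set of discrete variables."""

    assignment: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "DiscreteConfig":
        return cls(tuple(sorted(mapping.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def matches(self, record: Mapping[str, str]) -> bool:
        return all(record.get(k) == v for k, v in self.assignment)

    def __str__(self) -> str:
        return ", ".join(f"{k}={v}" for k, v in self.assignment) or "(marginal)"


def column_store(data: DataTable) -> dict[str, np.ndarray]:
    """Materialize float columns / integer code columns for fast reuse.

    Learning loops call the likelihood machinery thousands of times; going
    through pandas each time dominates the cost, so callers precompute this
    dict once per dataset.
    """
    store: dict[str, np.ndarray] = {}
    for spec in data.variables:
        if spec.is_discrete:
            store[spec.name] = data.codes(spec.name)
        else:
            store[spec.name] = data.column(spec.name).astype(float)
    return store
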