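"""Dataset, DAG and model serialization.

The dataset CSV schema is fixed: columns ``amen_kcal_kg, cp_pct, ee_pct,
ash_pct, cf_pct, category, ingredient, animal``, comma-delimited, UTF-8,
with a header row. Category ∈ {energy, protein}, ingredient ∈ {main,
byproduct, other} (main = corn for energy feeds, soybean for protein
feeds), animal ∈ {chick, cockerel}. The AMEn column may be absent in
prediction-only inputs. DAGs serialize as one ``parent -> child`` per line
under a ``nodes:`` header; fitted networks as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .fitting import CLGNetwork, LinearEquation, equations_frame
from .graph import DAG
from .reference import FEED_VARIABLES
from .validation import MetricsReport
from .variables import DataTable, DiscreteConfig, VariableSpec

COLUMN_TO_VARIABLE = {
    "amen_kcal_kg": "amen",
    "cp_pct": "cp",
    "ee_pct": "ee",
    "ash_pct": "ash",
    "cf_pct": "cf",
    "category": "category",
    "ingredient": "ingredient",
    "animal": "animal",
}
VARIABLE_TO_COLUMN = {v: k for k, v in COLUMN_TO_VARIABLE.items()}


def read_dataset(path, allow_missing_target: bool = False) -> DataTable:
    """Read and validate a feedstuff CSV against the fixed schema.

    Error messages cite the offending column and 1-based file line.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    required = set(COLUMN_TO_VARIABLE)
    if allow_missing_target and "amen_kcal_kg" not in raw.columns:
        required -= {"amen_kcal_kg"}
    missing = sorted(required - set(raw.columns))
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    unknown = sorted(set(raw.columns) - set(COLUMN_TO_VARIABLE))
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")
    variables = [
        v for v in FEED_VARIABLES
        if VARIABLE_TO_COLUMN[v.name] in raw.columns
    ]
    frame = pd.DataFrame()
    for spec in variables:
        col_name = VARIABLE_TO_COLUMN[spec.name]
        col = raw[col_name]
        if spec.is_discrete:
            bad = ~col.isin(spec.levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"{path}: column {col_name!r}, line {row + 2}: "
                    f"value {col.iloc[row]!r} not in {list(spec.levels)}"
                )
            frame[spec.name] = col
        else:
            vals = pd.to_numeric(col, errors="coerce")
            bad = ~np.isfinite(vals.to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ParseError(
                    f"{path}: column {col_name!r}, line {row + 2}: "
                    f"cannot parse {col.iloc[row]!r} as a finite number"
                )
            frame[spec.name] = vals
    return DataTable(variables, frame)


def write_dataset(data: DataTable, path) -> None:
    """Write a DataTable under the schema's column names, full precision."""
    out = data.df.rename(columns=VARIABLE_TO_COLUMN)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# DAG text format
# ---------------------------------------------------------------------------

def write_dag(dag: DAG, path) -> None:
    text = "nodes: " + ", ".join(dag.nodes) + "\n" + dag.format_arrows() + "\n"
    Path(path).write_text(text, encoding="utf-8")


def read_dag(path) -> DAG:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("nodes:"):
        raise ParseError(f"{path}: first line must be 'nodes: a, b, ...'")
    nodes = [n.strip() for n in lines[0][len("nodes:"):].split(",") if n.strip()]
    arrows = []
    for i, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "->" not in line:
            raise ParseError(f"{path}: line {i}: expected 'parent -> child'")
        parent, child = (part.strip() for part in line.split("->", 1))
        arrows.append((parent, child))
    return DAG(nodes, arrows)


# ---------------------------------------------------------------------------
# Fitted-network JSON
# ---------------------------------------------------------------------------

def network_to_dict(network: CLGNetwork) -> dict:
    return {
        "variables": [
            {"name": v.name, "kind": v.kind, "levels": list(v.levels), "units": v.units}
            for v in network.variables
        ],
        "arrows": sorted(network.dag.arrows),
        "discrete_locals": {
            node: {
                "parents": list(network.cpt_parents.get(node, ())),
                "rows": [
                    {"config": list(cfg), "probs": [float(p) for p in probs]}
                    for cfg, probs in cpt.items()
                ],
            }
            for node, cpt in network.discrete_locals.items()
        },
        "continuous_locals": {
            node: [
                {
                    "config": eq.config.as_dict(),
                    "intercept": eq.intercept,
                    "coefficients": eq.coefficients,
                    "residual_sd": eq.residual_sd,
                    "n_config": eq.n_config,
                    "dropped": sorted(eq.dropped),
                }
                for eq in eqs
            ]
            for node, eqs in network.continuous_locals.items()
        },
    }


def network_from_dict(payload: dict) -> CLGNetwork:
    variables = [
        VariableSpec(v["name"], v["kind"], tuple(v["levels"]), v.get("units", ""))
        for v in payload["variables"]
    ]
    dag = DAG([v.name for v in variables], [tuple(a) for a in payload["arrows"]])
    discrete_locals = {
        node: {
            tuple(row["config"]): np.asarray(row["probs"], dtype=float)
            for row in spec["rows"]
        }
        for node, spec in payload["discrete_locals"].items()
    }
    cpt_parents = {
        node: tuple(spec["parents"])
        for node, spec in payload["discrete_locals"].items()
    }
    continuous_locals = {
        node: [
            LinearEquation(
                DiscreteConfig.from_mapping(entry["config"]),
                float(entry["intercept"]),
                {k: float(v) for k, v in entry["coefficients"].items()},
                float(entry["residual_sd"]),
                int(entry["n_config"]),
                dropped=frozenset(entry.get("dropped", ())),
            )
            for entry in eqs
        ]
        for node, eqs in payload["continuous_locals"].items()
    }
    return CLGNetwork(variables, dag, discrete_locals, continuous_locals, cpt_parents)


def save_network(network: CLGNetwork, path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(network), indent=1), encoding="utf-8"
    )


def load_network(path) -> CLGNetwork:
    return network_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# Equation / metrics tables
# ---------------------------------------------------------------------------

def write_equations_csv(network: CLGNetwork, target: str, path) -> None:
    """Equation table CSV: dropped covariates as '-', full precision numbers."""
    frame = equations_frame(network, target)
    frame = frame.astype(object).where(frame.notna(), "-")
    frame.to_csv(path, index=False)


def write_metrics_csv(report: MetricsReport, path) -> None:
    pd.DataFrame([report.as_dict()]).to_csv(path, index=False)
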