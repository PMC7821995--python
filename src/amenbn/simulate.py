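"""Synthetic feedstuff data with the reference network's structure.

The meta-analysis behind the reference equations is not publicly deposited,
so this module generates datasets that emulate it: ancestral sampling down
the reference DAG, with the published per-configuration equations as the
default mean structure for AMEn, category proportions matching the study
(370 energy / 198 protein of 568), and composition distributions chosen to
reproduce the published summary envelope (min/mean/max of each covariate).
Continuous draws are truncated to those envelopes by per-variable rejection
sampling. Every simulation returns the generating :class:`CLGNetwork`
alongside the data, so structure- and parameter-recovery can be tested
against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .fitting import CLGNetwork, LinearEquation
from .reference import (
    ANIMAL_LEVELS,
    CATEGORY_LEVELS,
    FEED_VARIABLES,
    INGREDIENT_LEVELS,
    reference_dag,
    reference_equations,
)
from .variables import DataTable, DiscreteConfig

#: sampling order = a topological order of the reference DAG
_SAMPLING_ORDER = ("category", "animal", "ingredient", "cp", "ee", "cf", "ash", "amen")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth parameters for the feedstuff generator.

    Defaults encode the study conditions: 568 records, the observed
    energy/protein split, the published AMEn equations with a residual SD
    of 150 kcal/kg, and composition envelopes from the published training
    summaries. Distribution *shapes* (truncated Gaussians per category, a
    linear ash model) are generator conventions, configurable here.
    """

    n: int = 568
    seed: int = 0
    category_probs: tuple[float, float] = (370 / 568, 198 / 568)  # energy, protein
    # category-specific mixes keep every reference arrow a real dependence
    ingredient_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "energy": (0.55, 0.30, 0.15),  # main, byproduct, other
            "protein": (0.45, 0.25, 0.30),
        }
    )
    animal_probs: tuple[float, float] = (0.6, 0.4)  # chick, cockerel
    # per-category (mean, sd) for crude protein: energy feeds ~10%, protein ~49%
    cp_by_category: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"energy": (9.5, 4.0), "protein": (49.0, 10.0)}
    )
    cp_bounds: tuple[float, float] = (1.470, 71.440)
    ee_mean_sd: tuple[float, float] = (4.87, 4.0)
    ee_bounds: tuple[float, float] = (0.030, 26.210)
    cf_mean_sd: tuple[float, float] = (4.93, 4.5)
    cf_bounds: tuple[float, float] = (0.020, 26.500)
    # ash = intercept + b_cp·CP + b_cf·CF + noise
    ash_model: tuple[float, float, float, float] = (1.0, 0.08, 0.14, 1.0)
    ash_bounds: tuple[float, float] = (0.300, 12.610)
    amen_residual_sd: float = 150.0
    amen_bounds: tuple[float, float] = (1170.0, 4386.0)
    target_equations: tuple[LinearEquation, ...] | None = None
    truncate: bool = True

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        def _check_probs(name, probs):
            probs = np.asarray(probs, dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} probabilities must be >= 0 and sum to 1")
        _check_probs("category", self.category_probs)
        _check_probs("animal", self.animal_probs)
        for cat in CATEGORY_LEVELS:
            _check_probs(f"ingredient[{cat}]", self.ingredient_probs[cat])
        for name in ("cp_bounds", "ee_bounds", "cf_bounds", "ash_bounds", "amen_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name}: need min < max, got ({lo}, {hi})")
        for name in ("ee_mean_sd", "cf_mean_sd"):
            if getattr(self, name)[1] <= 0:
                raise ConfigError(f"{name}: sd must be > 0")
        if self.amen_residual_sd <= 0 or self.ash_model[3] <= 0:
            raise ConfigError("residual SDs must be > 0")

    def equations(self) -> list[LinearEquation]:
        if self.target_equations is not None:
            return list(self.target_equations)
        return reference_equations(self.amen_residual_sd)


def build_network(config: GeneratorConfig | None = None) -> CLGNetwork:
    """Assemble the generating CLG network implied by a generator config."""
    config = config or GeneratorConfig()
    config.validate()
    eqs_cp = [
        LinearEquation(
            DiscreteConfig.from_mapping({"category": cat}),
            config.cp_by_category[cat][0], {}, config.cp_by_category[cat][1], 0,
        )
        for cat in CATEGORY_LEVELS
    ]
    a0, b_cp, b_cf, a_sd = config.ash_model
    locals_cont = {
        "cp": eqs_cp,
        "ee": [LinearEquation(DiscreteConfig(), config.ee_mean_sd[0], {},
                             config.ee_mean_sd[1], 0)],
        "cf": [LinearEquation(DiscreteConfig(), config.cf_mean_sd[0], {},
                              config.cf_mean_sd[1], 0)],
        "ash": [LinearEquation(DiscreteConfig(), a0, {"cp": b_cp, "cf": b_cf}, a_sd, 0)],
        "amen": config.equations(),
    }
    locals_disc = {
        "category": {(): np.asarray(config.category_probs, dtype=float)},
        "animal": {(): np.asarray(config.animal_probs, dtype=float)},
        "ingredient": {
            (cat,): np.asarray(config.ingredient_probs[cat], dtype=float)
            for cat in CATEGORY_LEVELS
        },
    }
    return CLGNetwork(
        FEED_VARIABLES, reference_dag(), locals_disc, locals_cont,
        cpt_parents={"category": (), "animal": (), "ingredient": ("category",)},
    )


def reference_network(residual_sd: float = 150.0) -> CLGNetwork:
    """The reference network fixture: reference DAG + the 12 published equations.

    CPTs and composition models take the generator defaults; ``residual_sd``
    sets the AMEn noise level for simulation.
    """
    return build_network(replace(GeneratorConfig(), amen_residual_sd=residual_sd))


def _truncated_normal(rng, mean, sd, bounds, truncate, max_tries=1000):
    mean = np.asarray(mean, dtype=float)
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)
    x = rng.normal(mean, sd)
    if not truncate:
        return x
    lo, hi = bounds
    for _ in range(max_tries):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = rng.normal(mean[bad], sd[bad])
    return np.clip(x, lo, hi)


def sample_network(
    network: CLGNetwork,
    n: int,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    forced_discrete: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> DataTable:
    """Ancestral sampling of n records from any CLG network.

    Nodes are visited in topological order: discrete nodes draw from their
    CPT row for each realized parent configuration, continuous nodes from
    the matching per-configuration linear Gaussian. ``bounds`` optionally
    truncates named continuous variables (rejection sampling, clipped after
    1000 rounds); ``forced_discrete`` pins discrete columns instead of
    sampling them.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    bounds = bounds or {}
    if forced_discrete is not None:
        n = len(forced_discrete)
    cols: dict[str, np.ndarray] = {}
    for node in network.dag.topological_order():
        spec = network.specs[node]
        if spec.is_discrete:
            if forced_discrete is not None and node in forced_discrete.columns:
                vals = forced_discrete[node].astype(str).to_numpy()
                if not set(vals) <= set(spec.levels):
                    raise ConfigError(f"forced {node!r} outside declared levels")
                cols[node] = vals
                continue
            cpt = network.discrete_locals[node]
            parents = network.cpt_parents.get(node, ())
            levels = np.asarray(spec.levels)
            out = np.empty(n, dtype=object)
            for cfg, probs in cpt.items():
                mask = np.ones(n, dtype=bool)
                for pname, level in zip(parents, cfg):
                    mask &= cols[pname] == level
                k = int(mask.sum())
                if k:
                    out[mask] = levels[rng.choice(len(levels), size=k, p=probs)]
            cols[node] = out.astype(str) if n else np.empty(0, dtype=str)
        else:
            mean = np.zeros(n)
            sd = np.zeros(n)
            matched = np.zeros(n, dtype=bool)
            for eq in network.continuous_locals[node]:
                cfg = eq.config.as_dict()
                mask = np.ones(n, dtype=bool)
                for k_, v in cfg.items():
                    mask &= cols[k_] == v
                if not mask.any():
                    continue
                mu = np.full(int(mask.sum()), eq.intercept)
                for cov, coef in eq.coefficients.items():
                    mu += coef * cols[cov][mask].astype(float)
                mean[mask] = mu
                sd[mask] = eq.residual_sd
                matched[mask] = True
            if n and not matched.all():
                raise ConfigError(f"no generating equation for some rows of {node!r}")
            if n:
                cols[node] = _truncated_normal(
                    rng, mean, sd, bounds.get(node, (-np.inf, np.inf)),
                    node in bounds,
                )
            else:
                cols[node] = np.empty(0)
    df = pd.DataFrame({v.name: cols[v.name] for v in network.variables})
    return DataTable(network.variables, df)


def simulate_feed_dataset(
    config: GeneratorConfig | None = None,
    forced_discrete: pd.DataFrame | None = None,
) -> tuple[DataTable, CLGNetwork]:
    """Sample a feedstuff dataset plus its generating network.

    ``forced_discrete`` (columns category, animal, ingredient) pins the
    discrete configuration per row instead of sampling it, which is how the
    balanced per-configuration designs are produced. Deterministic given
    ``config.seed``.
    """
    config = config or GeneratorConfig()
    network = build_network(config)
    bounds = (
        {
            "cp": config.cp_bounds, "ee": config.ee_bounds, "cf": config.cf_bounds,
            "ash": config.ash_bounds, "amen": config.amen_bounds,
        }
        if config.truncate
        else None
    )
    data = sample_network(
        network, config.n, seed=config.seed, bounds=bounds,
        forced_discrete=forced_discrete,
    )
    return data, network


def simulate_balanced(
    config: GeneratorConfig | None = None, n_per_config: int = 2000
) -> tuple[DataTable, CLGNetwork]:
    """Equal rows for each of the 12 category × animal × ingredient configs."""
    config = config or GeneratorConfig()
    rows = []
    for cat in CATEGORY_LEVELS:
        for animal in ANIMAL_LEVELS:
            for ingr in INGREDIENT_LEVELS:
                rows.extend(
                    {"category": cat, "animal": animal, "ingredient": ingr}
                    for _ in range(n_per_config)
                )
    return simulate_feed_dataset(config, forced_discrete=pd.DataFrame(rows))
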