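"""The published AMEn prediction network used as reference and ground truth.

Variables
---------
Eight variables describe a feedstuff record: nitrogen-corrected apparent
metabolizable energy (``amen``, kcal/kg), the proximate-composition
covariates crude protein (``cp``), ether extract (``ee``), ash and crude
fiber (``cf``, all % of feed), and three discrete factors — feed
``category`` (energy vs protein concentrate), ``ingredient`` within the
category (main ingredient: corn or soybean; by-products; others) and the
bioassay ``animal`` (chick vs cockerel).

The reference DAG encodes the factorization

    P(amen, cp, ee, ash, cf, category, ingredient, animal) =
        P(ee)·P(cf)·P(category)·P(animal)·P(cp|category)·
        P(ingredient|category)·P(ash|cp,cf)·P(amen|everything else)

— eight nodes, eleven arrows, and a seven-node Markov blanket around the
target. The twelve reference equations (one per category × animal ×
ingredient configuration) carry the published coefficients; the corn
by-products / cockerel configuration retains only CP and EE, its ash and CF
terms being non-estimable (dropped).
"""

from __future__ import annotations

from .fitting import LinearEquation
from .graph import DAG, add_arrow
from .variables import DiscreteConfig, VariableSpec

CATEGORY_LEVELS = ("energy", "protein")
INGREDIENT_LEVELS = ("main", "byproduct", "other")
ANIMAL_LEVELS = ("chick", "cockerel")

#: display labels used when rendering equations for humans
DISPLAY_NAMES = {"amen": "AMEn", "cp": "CP", "ee": "EE", "ash": "ash", "cf": "CF"}

FEED_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("amen", "continuous", units="kcal/kg"),
    VariableSpec("cp", "continuous", units="%"),
    VariableSpec("ee", "continuous", units="%"),
    VariableSpec("ash", "continuous", units="%"),
    VariableSpec("cf", "continuous", units="%"),
    VariableSpec("category", "discrete", CATEGORY_LEVELS),
    VariableSpec("ingredient", "discrete", INGREDIENT_LEVELS),
    VariableSpec("animal", "discrete", ANIMAL_LEVELS),
)

FEED_SPECS = {v.name: v for v in FEED_VARIABLES}

#: arrows of the reference DAG, in a build order with no transient cycles
REFERENCE_ARROWS: tuple[tuple[str, str], ...] = (
    ("category", "cp"),
    ("category", "ingredient"),
    ("cp", "ash"),
    ("cf", "ash"),
    ("cp", "amen"),
    ("ee", "amen"),
    ("ash", "amen"),
    ("cf", "amen"),
    ("category", "amen"),
    ("ingredient", "amen"),
    ("animal", "amen"),
)


def reference_dag() -> DAG:
    """The fixed 8-node, 11-arrow DAG implied by the reference factorization."""
    dag = DAG([v.name for v in FEED_VARIABLES])
    for parent, child in REFERENCE_ARROWS:
        dag = add_arrow(dag, parent, child, FEED_SPECS)
    return dag


# (category, animal, ingredient) -> (intercept, cp, ee, ash, cf); None = dropped
REFERENCE_COEFFICIENTS: dict[tuple[str, str, str], tuple] = {
    ("energy", "chick", "main"): (3658.16, -2.41, -11.25, 83.41, 16.76),
    ("energy", "chick", "byproduct"): (4209.57, -34.56, 32.84, -25.15, -142.57),
    ("energy", "chick", "other"): (4335.88, -50.91, 35.40, -67.35, -87.06),
    ("protein", "chick", "main"): (3684.83, -19.84, -71.15, 18.14, -8.93),
    ("protein", "chick", "byproduct"): (2951.05, 0.09, 37.96, 5.04, -17.60),
    ("protein", "chick", "other"): (2327.69, 24.23, 77.72, -167.06, -22.28),
    ("energy", "cockerel", "main"): (3321.82, 51.31, 39.42, -377.11, 113.92),
    ("energy", "cockerel", "byproduct"): (4716.45, -227.63, 144.47, None, None),
    ("energy", "cockerel", "other"): (4133.39, -89.45, 100.32, -5.50, -96.37),
    ("protein", "cockerel", "main"): (4143.45, -3.18, -43.45, -213.55, 6.71),
    ("protein", "cockerel", "byproduct"): (518.54, 26.25, 47.10, 184.42, 69.0),
    ("protein", "cockerel", "other"): (6033.28, -15.02, -105.81, -556.50, 91.23),
}

_COVARIATES = ("cp", "ee", "ash", "cf")


def reference_equations(residual_sd: float = 150.0) -> list[LinearEquation]:
    """The twelve reference AMEn equations as :class:`LinearEquation` objects.

    ``residual_sd`` (kcal/kg) attaches a noise level for simulation; the
    published table reports only the mean structure.
    """
    equations = []
    for (cat, animal, ingr), row in REFERENCE_COEFFICIENTS.items():
        intercept, *coefs = row
        coefficients = {
            cov: c for cov, c in zip(_COVARIATES, coefs) if c is not None
        }
        dropped = frozenset(
            cov for cov, c in zip(_COVARIATES, coefs) if c is None
        )
        equations.append(
            LinearEquation(
                config=DiscreteConfig.from_mapping(
                    {"category": cat, "animal": animal, "ingredient": ingr}
                ),
                intercept=intercept,
                coefficients=coefficients,
                residual_sd=residual_sd,
                n_config=0,
                dropped=dropped,
            )
        )
    return equations
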