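# amenbn

Conditional linear Gaussian (CLG) Bayesian networks for predicting the
nitrogen-corrected apparent metabolizable energy (**AMEn**, kcal/kg) of
broiler feedstuffs from their proximate composition.

Formulating balanced broiler rations requires the energy value of every
ingredient, but in-vivo metabolizable-energy assays are slow and expensive.
The practical alternative is a prediction equation driven by routinely
measured chemical composition: crude protein (CP), ether extract (EE), ash
and crude fiber (CF), together with the feed category (energy vs protein
concentrate), the ingredient within the category (corn/soybean, by-products,
others) and the bioassay animal (chick vs cockerel). `amenbn` implements the
Bayesian-network route to such equations end to end, for nutrition
researchers and for anyone who needs hybrid (mixed discrete/continuous)
network learning with per-configuration regression output.

## The model

A Bayesian network over variables X₁…Xₚ factorizes the joint distribution
along a DAG,

    P(X₁, …, Xₚ) = ∏ᵢ P(Xᵢ | Pa(Xᵢ)).

With mixed variables the network is *conditional linear Gaussian*: discrete
nodes have only discrete parents (multinomial CPTs), and each continuous
node X_j follows, per joint configuration *d* of its discrete parents,

    X_j | Pa_D = d, Pa_C = x  ~  N( β₀(d) + β(d)ᵀx, σ²(d) ).

For an AMEn target whose discrete parents are category × animal ×
ingredient this yields 2 × 2 × 3 = 12 linear prediction equations — the
artifact a nutritionist actually uses.

The structure is learned from data by **MMHC** (max-min hill climbing):

1. *Constraint phase* — **MMPC** discovers each node's candidate
   parents-and-children set by max-min association with subset-conditioned
   independence tests (G² for discrete pairs, Fisher's z for continuous
   pairs, a conditional-Gaussian likelihood ratio for mixed ones), then an
   AND-symmetry correction builds an undirected skeleton.
2. *Score phase* — greedy **hill climbing** over add/delete/reverse arrow
   moves, restricted to skeleton edges and maximizing the decomposable
   CLG-**BIC** score ∑ [ℓ_local − (k_local/2)·ln n].

**RSMAX2** generalizes the recipe to any restrict/maximize pair; with the
bundled MMPC + hill-climbing plugins it coincides with MMHC. Because the raw
568-experiment meta-analysis behind the reference equations is not publicly
deposited, the package ships a synthetic-data generator that emulates its
structure (category proportions, composition envelopes, and the published
equations as configurable ground truth), so that learning, fitting and
validation are all testable against a known generating network.

## Worked example

```python
import amenbn as a
from amenbn.model import CLGModel

data, truth = a.simulate_feed_dataset(a.GeneratorConfig(n=568, seed=1))
train, test = a.train_test_split(data, 0.8, seed=1)   # 454 / 114 records

res = CLGModel(train).fit(structure="mmhc", alpha=0.05, seed=1)
print(res.summary())
print(res.validate(test, "amen"))
```

prints (abridged)

```
Conditional linear Gaussian Bayesian network
============================================================
n obs:          454
nodes:          8
arrows:         8
structure:      mmhc
CI tests:       75
...
P(amen, cp, ee, ash, cf, category, ingredient, animal) = P(animal) ·
P(category) · P(cf) · P(cp | category) · P(ash | cf, cp) · P(ee) ·
P(ingredient | category) · P(amen | animal, category, cp, ingredient)

Prediction equations for amen:
category   animal ingredient intercept      cp residual_sd  n_config
  energy    chick       main   3820.14    9.73      192.35        91
  ...
n=114  r=0.8971  R2=0.8048  MSE=111064.34  MAD=255.89  MAPE=8.86%  bias=-16.52  PMSE=333.26
```

At n = 454 the learner keeps only the strongest AMEn parents (category,
animal, ingredient, CP); with more data it recovers the full 11-arrow
reference structure. The validation line reports Pearson r and R² of
predicted vs observed AMEn, mean squared error (MSE, kcal²/kg²), mean
absolute deviation (MAD), mean absolute percentage error (MAPE, %), mean
bias (predicted − observed) and PMSE = √MSE, all on the held-out 20%.

The package also ships the fixed reference network with the twelve published
equations, usable directly for prediction:

```python
eqs = a.extract_equations(a.reference_network(), "amen")
print(a.render_equation(eqs[0], "amen", a.reference.DISPLAY_NAMES))
# AMEn = 3658.16 - 2.41 CP - 11.25 EE + 83.41 ash + 16.76 CF
rec = {"category": "energy", "animal": "chick", "ingredient": "main",
       "cp": 8.26, "ee": 3.61, "ash": 1.26, "cf": 1.73}
print(a.predict_target(eqs, rec))   # 3731.732 kcal/kg
```

A `simulate → learn → fit → equations → predict → validate` pipeline is
also available from the shell via the `amenbn` command; see `amenbn --help`.

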