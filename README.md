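# ionrecipe

Salt recipes for exact ion solutions, and ion-confounding-free experiments.

Biologists who culture cells, microbes or plants in defined media face two
recurring problems. First, *reconstruction*: given the ion analysis of a
soil solution, lake water or tissue, find the mixture of salts that
reproduces every ion concentration exactly — nearly impossible by hand,
because each salt delivers its ions in fixed ratios. Second,
*ion-specific experiments*: varying a salt to study one ion co-varies its
counter-ion (varying KCl confounds K⁺ with Cl⁻), so ion effects must be
designed at the ion level and each treatment converted into a recipe
afterwards.

`ionrecipe` solves both. Recipe construction is a linear program

```
minimize  c·X    subject to   A·X (=, ≤, ≥) b ,   X ≥ 0
```

where `X` are unknown salt amounts (mM), `a_ij` the moles of ion *i*
released per mole of salt *j*, and `b` the target ion concentrations (mM).
Ion-based experiments use Scheffé mixture designs: for two components the
quadratic model `y = b₁x₁ + b₂x₂ + b₁₂x₁x₂` (no intercept, x₁+x₂=1) with
D-optimal point selection, replication for pure error, and the full
lack-of-fit ANOVA.

The package provides:

* a chemical core (formula/hydrate parsing, pinned atomic weights,
  electroneutrality-validated salt dissociations) and a built-in catalog of
  30 common media salts, extensible via CSV;
* the recipe LP with forced salts, free species (H⁺/OH⁻/chelators), pooled
  targets (e.g. total phosphate), deterministic tie-breaking among optimal
  recipes, and an infeasibility diagnosis (charge imbalance in meq/L,
  unreachable ions, least-infeasible suggestion);
* deconstruction of any recipe into its ion composition, percent-deviation
  reports and charge balance;
* D-optimal mixture design generation and its translation into per-point
  ion target specs that differ *only* in the ions under study;
* Scheffé model fitting with sequential linear/quadratic ANOVA and
  lack-of-fit vs pure-error partition;
* a seeded generator of random feasible problems for property testing.

## Worked example

Reconstruct a loamy-soil solution from its ion analysis
(`examples/01_soil_solution_recipe.py`):

```python
from ionrecipe import build_lp, deconstruct, percent_deviation, solve
from ionrecipe.catalog import builtin_catalog
from ionrecipe.fixtures import soil_catalog, soil_target_spec

catalog = builtin_catalog()
spec = soil_target_spec()          # 10 ion targets; H+/OH-/EDTA free
recipe = solve(build_lp(spec, soil_catalog(catalog)))
```

prints

```
solver status: optimal (total dissolved salts 6.7250 mmol/L)
salt                    mM        mg/L
(NH4)2SO4           0.2000     26.4268
CaSO4.2H2O          2.2750    391.6731
K2SO4               0.1500     26.1379
Mg(NO3)2.6H2O       2.3500    602.5471
MgCl2.6H2O          0.9500    193.1303
MgSO4.7H2O          0.1000     24.6466
Na2FeEDTA.2H2O      0.0200      8.5212
Na2HPO4             0.0050      0.7098
Na2SO4              0.6750     95.8740
```

and the verification (deconstructing the recipe and comparing to the
targets) shows every ion deviation at 0% — e.g. 4.700 mM NO₃⁻, 0.400 mM
NH₄⁺, 0.005 mM total phosphate achieved exactly. A historical
hand-formulated approximation of the same analysis missed individual ions
by −68% to +900%; the LP makes the reconstruction exact. (Calcium is
targeted at its 2.275 mM mass-balance level; see `docs/methods.md` for the
caveat about the source analysis's calcium row.)

Fitting the packaged 13-run K⁺/Na⁺ substitution experiment
(`examples/04_fit_growth_anova.py`) prints the mixture ANOVA:

```
Source                  SS  df        MS       F        p
Model              1.7E+06   2  8.51E+05   45.44  <0.0001
Linear mixture    1.01E+06   1  1.01E+06   53.92  <0.0001
Quadratic         6.92E+05   1  6.92E+05   36.97   0.0001
Residual          1.87E+05  10  1.87E+04
Lack of Fit       6.52E+04   2  3.26E+04    2.14   0.1802
Pure Error        1.22E+05   8  1.52E+04
Cor Total         1.89E+06  12
```

with vertex estimates 1010.6% (all-K) and 251.1% (all-Na) fresh-weight
growth and a significant positive blending term (2112.7): sodium
substitutes for potassium over a wide range but cannot replace it at the
all-Na vertex.

## Command line

A thin CLI wraps the library:

```sh
ionrecipe solve --targets targets.yaml --catalog builtin --out results/
ionrecipe deconstruct --recipe recipe.csv --units mg_per_l
ionrecipe design --components Na+,K+ --total 23.2 --lof 2 --reps 8
ionrecipe fit --observations growth.csv
ionrecipe reproduce          # re-derive the packaged worked examples
ionrecipe synth --seed 1     # emit a random feasible test problem
```

Exit codes: 0 success, 2 infeasible (a diagnosis file explains why and
suggests the closest achievable composition), 3 validation error.

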