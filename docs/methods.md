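# Methods

## The problem

Dissolved salts deliver ions in fixed ratios: 1 mM KCl is 1 mM K⁺ *and*
1 mM Cl⁻.  Two consequences drive this package:

1. **Formulating a solution to match an ion analysis** (a soil solution, a
   lake water, a tissue extract) means finding non-negative salt amounts
   whose combined dissociation hits every analyzed ion level.  Done by
   hand this is rarely exact.
2. **Studying a specific ion's effect** requires varying *only* that ion.
   Varying a salt co-varies its counter-ion (ion confounding), so the
   experiment must be designed at the ion level and each treatment
   translated into a salt recipe afterwards.

## Recipe solving as a linear program

Let `A` be the ion-proportionality matrix (`a_ij` = mol of ion *i* per mol
of salt *j*, from each salt's dissociation map), `b` the target
concentrations (mM), `c` per-salt weights.  The solver computes

```
minimize    c·X
subject to  A X (=, ≤, ≥) b ,   X ≥ 0
```

Defaults: equality senses (the tool's purpose is *exact* reconstruction)
and `c_j = 1` on the mM scale, i.e. minimize total dissolved mmol of salts.
The weights are configurable per salt through the catalog CSV (e.g. mass
weights); nothing in the method depends on this choice, it only selects
among feasible recipes.

**Free species.**  Any mixture of neutral salts is electroneutral, so a
target vector with Σ z_i·b_i ≠ 0 is unreachable unless some charged species
is left unconstrained.  The conventional free set is {H⁺, OH⁻, EDTA²⁻,
EDTA⁴⁻}: it admits hydroxide salts (NaOH, NH₄OH, Ca(OH)₂), boric acid and
chelated-iron salts.  Every species a catalog salt could release that is
neither targeted, pooled into a target, nor freed is constrained to zero —
an explicit design choice that keeps the electroneutrality diagnosis sound
and prevents the optimizer from smuggling in untracked ions.

**Pooled targets.**  Phosphate speciation depends on pH, which this package
deliberately does not model; by default a single `PO4_total` target
constrains the sum of H₂PO₄⁻ + HPO₄²⁻ + PO₄³⁻ (and `Fe_total` pools the
iron charge states).  Species-resolved targeting remains available by
targeting the species symbols directly.

**Determinism.**  Recipes are generally not unique (degenerate optima are
the rule: several salts can deliver the same ion pair).  After finding the
optimal objective f\*, a secondary pass minimizes each salt amount in
catalog order subject to `c·X ≤ f* + 1e-9·max(1, |f*|)`, fixing each in
turn — the lexicographically smallest optimal recipe in catalog order.
Verification therefore always compares *achieved ion compositions*, never
recipe identity.

**Tolerances.**  HiGHS is run with primal feasibility 1e-10; an optimal
recipe must satisfy every equality row to |A·X − b| ≤ 1e-8·max(1, b_i),
and residuals above 1e-10 raise a warning.  All internal computation is in
mM; mg/L (= mM × molar mass) appears only at the I/O boundary.

**Infeasibility diagnosis** reports (a) the charge imbalance of the target
vector in meq/L (a range when a pooled target mixes member charges), which
with no charged free species is a necessary-condition violation; (b)
targeted species no catalog salt produces; (c) the least-infeasible recipe,
from an auxiliary LP minimizing the total absolute deviation.

## Chemistry bookkeeping

Atomic weights are an embedded table of IUPAC conventional values rounded
to 4 decimals, pinned so mg/L output is reproducible bit-for-bit.  Formulas
(with `.`/`*`/`·` hydrate suffixes and parentheses) are parsed by a small
recursive tokenizer.  Hydrate water counts toward molar mass but dissolves
as free water, not as a tracked species.  Salt validation checks
electroneutrality of the dissociation map, element conservation against the
parsed formula, and that species mass does not exceed the salt mass.

Two conventions deserve note:

* **Fe/EDTA.**  The ferric-sodium EDTA salt is modeled as
  2 Na⁺ + Fe²⁺ + EDTA⁴⁻ (net zero).  Published usage implies an effective
  molar mass of 426.06 g/mol for the dihydrate, which the summed atomic
  weights of Na₂FeC₁₀H₁₂N₂O₈·2H₂O match within 0.01; the catalog entry
  nevertheless carries 426.06 as an explicit override so delivered iron
  matches the published mg/L figures exactly.  The oxidation-state /
  protonation convention is a bookkeeping choice, not a chemical claim:
  with EDTA free, only the iron and sodium rows feel it.
* **NH₄OH** is taken at face value as NH₄⁺ + OH⁻, which is what the
  published media mass balances require.

## The packaged soil-reconstruction case and its calcium caveat

The bundled soil-solution analysis lists ten ions including Ca²⁺ =
12.4 mM.  The published ten-salt recipe, converted back to mM, matches
nine of the ten targets to better than 0.02% — but delivers only ~2.50 mM
calcium.  The calcium row is internally inconsistent in the source data and
is treated as follows:

* The reproduction fixture targets Ca²⁺ = **2.275 mM**, the unique level
  the ten-salt mass balance admits once the other nine targets are fixed
  and hydroxide contributes no calcium (the sulfate budget leaves exactly
  2.275 mM for CaSO₄·2H₂O and the optimum takes Ca(OH)₂ = 0).  The
  published recipe's extra 0.225 mM Ca(OH)₂ (hence ~2.50 mM Ca and
  0.45 mM free OH⁻) is a non-minimal but equally target-satisfying
  solution for the nine other ions.
* Recipe verification excludes calcium; the discrepancy is flagged in the
  reproduction report rather than silently absorbed.
* Targeting the printed 12.4 mM with nothing freed is infeasible by
  ~+20.3 meq/L of unmatched cation charge — the worked example for the
  infeasibility diagnosis.

## Mixture designs

Blends live on the simplex (proportions summing to 1).  The Scheffé bases
have no intercept; for two components the quadratic model is
`y = b1·x1 + b2·x2 + b12·x1·x2`, where b1, b2 are the vertex responses and
b12 the nonlinear-blending coefficient.  D-optimal selection maximizes
det(XᵀX) over subsets of a finite candidate set — exhaustively up to 10⁶
subsets, otherwise by seeded multi-start Fedorov exchange restricted to
distinct candidates (so it searches the same subset space and is verified
against the exhaustive result on small sets).  Ties break to the earliest
subset in candidate order.  Defaults follow the packaged experiment: five
equally spaced candidate blends, 3 model + 2 lack-of-fit points, and 8
replicates allocated round-robin over the distinct blends, vertices first
in design order, yielding the replication pattern (3,2,3,2,3).  The source
experiment does not state how its 8 replicates were distributed; this
allocation reproduces its realized 13-point support and is documented as a
reproduction choice.

`blend_to_targets` turns a blend into a full target spec: pooled ion *k*
gets `x_k × pool_total` while the base spec's ions pass through unchanged,
so specs across a design differ only in the pooled ions.  The 23.2 mM
K⁺+Na⁺ pool of the packaged experiment is the 20.25 mM MS level plus a
2.95 mM Na⁺ offset replacing the NaOH pH-adjustment step; offsets of this
kind are folded into `pool_total` by the user — no pH chemistry is
computed.

**Realized-recipe caveat.**  The published whole-mg recipes for the five
media realize the K/Na blends with a 0.2 mM floor on each component
(vertices at 23/0.2 mM rather than 23.2/0), so the realized K⁺ and Na⁺
levels deviate from the idealized blend table by up to ~1.7% at four of
five media, while the seven constant ions, the 23.2 mM pool and the
96.55 mM ion sums all verify within 0.5%.  One acceptance test asserts the
idealized per-ion agreement and is expected to fail on exactly those K/Na
entries; the reconciled relationship is verified by a separate passing
test.

## Mixture ANOVA

For N observations and p model terms: corrected total SS on N−1 df; the
model line carries p−1 df (the simplex constraint costs one); the
sequential split fits the linear-only model first (q−1 df above the grand
mean) and assigns the increment to the quadratic term(s).  Pure error is
the within-blend SS over replicated blends (df = N − #distinct blends) and
is invariant to the fitted model; lack of fit is the residual minus pure
error.  F ratios use the residual MS, except lack of fit, tested against
pure error; p-values are upper-tail F probabilities, displayed as
"<0.0001" below 1e-4 (full precision in machine output).  Mean squares
below 1e-12 × total SS are treated as zero and the corresponding F
reported as undefined rather than as a huge ratio.  Coefficients display
as integers and SS to 3 significant figures in the text report; CSV/JSON
carry full precision.  No response transformation is applied by default
(the packaged dataset needed none); the fit operates on whatever response
column it is given.

On the packaged 13-observation dataset the fit must use the 13
dish-averaged points, not the 78 individual dishes: the residual (10) and
total (12) degrees of freedom force that interpretation.

## Synthetic problems: what they do and do not emulate

`generate_synthetic_problem` samples ions with charges ±1..3, builds salts
as charge-balanced cation/anion pairs, draws a random sparse recipe and
uses its deconstruction as the target — so feasibility is guaranteed by
construction and the solve→deconstruct round-trip has a known answer.
This exercises the LP machinery (degeneracy, pooling-free paths,
determinism) under realistic stoichiometry, but *not* formula parsing,
hydrates, pooled targets, free species, or mg/L conversion, which are
covered by the real-catalog fixtures.  Passing synthetic tests therefore
demonstrates solver correctness, not chemistry-table correctness.

Default sizes (6 salts, 5 ions, amounts U(0,10) mM with 30% structural
zeros) keep each problem at the scale of real media catalogs; the
property suite runs 100 seeds in well under a second.

## Known limitations

* No pH, activity, ionic-strength or speciation chemistry: phosphate (and
  carbonate, if added) is handled as a pooled total; hydroxide/proton
  release is tracked stoichiometrically only.
* One configured charge per species symbol; transition-metal redox states
  are separate symbols, not equilibria.
* No solubility limits, costs, or stock-solution rounding: an optimal
  recipe may be impractical to weigh; amounts are exact reals.
* D-optimal search over the continuous simplex is out of scope; candidates
  are finite sets.
* The ANOVA is the classical fixed-effects decomposition; no
  studentized-residual diagnostics beyond the residual vector itself.
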