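"""Reconstruct a loamy-soil solution exactly from its ion analysis.

Builds the packaged soil-solution ion targets (nine ions plus calcium at
its mass-balance level), solves the recipe LP over the ten-salt catalog,
and verifies by deconstruction that every target is met exactly — the
problem a hand-formulated medium historically missed by 41-900% per ion.
"""

from ionrecipe import build_lp, deconstruct, percent_deviation, solve
from ionrecipe.catalog import builtin_catalog
from ionrecipe.fixtures import soil_catalog, soil_target_spec

catalog = builtin_catalog()
spec = soil_target_spec()

recipe = solve(build_lp(spec, soil_catalog(catalog)))
print(f"solver status: {recipe.status} "
      f"(total dissolved salts {recipe.objective:.4f} mmol/L)")
print(f"{'salt':<16}{'mM':>10}{'mg/L':>12}")
for salt, mM in recipe.nonzero().items():
    print(f"{salt:<16}{mM:>10.4f}{mM * catalog[salt].molar_mass:>12.4f}")

achieved = deconstruct(recipe, catalog)
devs = percent_deviation(achieved, spec.targets, catalog.registry)
print("\nverification (achieved vs target, % deviation):")
for ion, target in spec.targets.items():
    got = achieved.resolve(ion, catalog.registry)
    print(f"  {ion:<10} target {target:>8.3f} mM  achieved {got:>8.3f} mM  "
          f"dev {devs[ion]:+.2e}%")
print("\nEvery deviation is ~0: the linear program meets the ion analysis "
      "exactly, which is not generally possible by hand.")
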