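"""Design an ion-confounding-free K+/Na+ substitution experiment.

Selects a D-optimal 2-component quadratic mixture design over five
candidate blends, augments it with lack-of-fit points and replicates
(13 runs total), and expands each blend into a full ion target spec with
the K+Na pool at 23.2 mM and all other MS macro-ions constant.  Each
point's spec is then solved into an actual salt recipe.
"""

from ionrecipe import (TargetSpec, augment, blend_to_targets, build_lp,
                       d_optimal_select, default_candidates, solve)
from ionrecipe.catalog import builtin_catalog
from ionrecipe.fixtures import KNA_POOL_TOTAL_MM, ms_base_targets

candidates = default_candidates(q=2, levels=5)
model_points = d_optimal_select(candidates, degree=2, n_points=3)
design = augment(model_points, n_lof=2, n_reps=8, candidates=candidates)
print(f"design: {len(design.points)} points "
      f"({design.counts_by_role()}), distinct blends and replication:")
for blend, reps in design.replication().items():
    print(f"  Na {blend[0]:.2f} / K {blend[1]:.2f}  x{reps}")

base = TargetSpec.paper_faithful(ms_base_targets())
catalog = builtin_catalog()
print("\nper-blend ion targets (mM) and a solved recipe size:")
for blend in design.distinct_blends():
    spec = blend_to_targets(blend, KNA_POOL_TOTAL_MM, ["Na+", "K+"], base)
    recipe = solve(build_lp(spec, catalog))
    assert recipe.status == "optimal"
    print(f"  Na {spec.targets['Na+']:>5.1f}  K {spec.targets['K+']:>5.1f}  "
          f"others fixed -> {len(recipe.nonzero())} salts, "
          f"{recipe.objective:.2f} mmol/L total")
print("\nOnly Na+ and K+ change between points (their sum fixed at "
      f"{KNA_POOL_TOTAL_MM} mM); every other ion is identical, so any "
      "response difference is attributable to the K+/Na+ substitution.")
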