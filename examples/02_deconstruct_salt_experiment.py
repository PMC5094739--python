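"""Expose ion confounding in a classic two-salt experiment.

Deconstructs a published wheat study that varied KCl and NaCl to probe
K+/Na+ effects: the chloride column shows Cl- co-varies perfectly with the
cations, so cation effects cannot be separated from chloride's.
"""

from ionrecipe import charge_balance, deconstruct
from ionrecipe.catalog import builtin_catalog
from ionrecipe.fixtures import load_wheat_treatments

catalog = builtin_catalog()
print(f"{'treatment':>9}{'KCl mM':>8}{'NaCl mM':>9}"
      f"{'K+':>8}{'Na+':>8}{'Cl-':>8}{'sum mM':>9}")
for _, row in load_wheat_treatments().iterrows():
    comp = deconstruct({"KCl": row["KCl_mM"], "NaCl": row["NaCl_mM"]}, catalog)
    assert abs(charge_balance(comp, catalog.registry)) < 1e-12
    print(f"{int(row['treatment']):>9}{row['KCl_mM']:>8.2f}{row['NaCl_mM']:>9.2f}"
          f"{comp['K+']:>8.2f}{comp['Na+']:>8.2f}{comp['Cl-']:>8.2f}"
          f"{comp.total(('K+', 'Na+', 'Cl-')):>9.2f}")
print("\nCl- always equals K+ + Na+ (salts are neutral), so the design "
      "confounds every cation contrast with chloride: it compares salts, "
      "not ions.")
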