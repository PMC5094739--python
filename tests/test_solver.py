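"""Recipe LP: assembly, solving, determinism, diagnosis, unit conversion."""

import itertools

import numpy as np
import pytest

from ionrecipe import (TargetSpec, build_lp, charge_balance, deconstruct,
                       diagnose_infeasibility, solve, to_mg_per_l)
from ionrecipe.catalog import CatalogError
from ionrecipe.fixtures import SOIL_CA_MM, soil_catalog, soil_target_spec
from ionrecipe.solver import UnreachableIonError
from ionrecipe.synth import generate_synthetic_problem


@pytest.fixture
def two_salt(catalog):
    return catalog.subset(["KCl", "NaCl"])


def test_build_lp_two_salt_matrix(two_salt):
    spec = TargetSpec(targets={"K+": 0.54, "Na+": 8.7, "Cl-": 9.24})
    problem = build_lp(spec, two_salt)
    assert problem.rows == ["K+", "Na+", "Cl-"]
    assert problem.A.tolist() == [[1, 0], [0, 1], [1, 1]]
    assert problem.b.tolist() == [0.54, 8.7, 9.24]
    assert problem.senses == ["=", "=", "="]


def test_solve_square_system_unique(two_salt):
    spec = TargetSpec(targets={"K+": 0.54, "Na+": 8.7, "Cl-": 9.24})
    recipe = solve(build_lp(spec, two_salt))
    assert recipe.status == "optimal"
    assert recipe.amounts["KCl"] == pytest.approx(0.54, abs=1e-9)
    assert recipe.amounts["NaCl"] == pytest.approx(8.7, abs=1e-9)


def test_empty_targets_give_zero_recipe(catalog):
    recipe = solve(build_lp(TargetSpec(), catalog))
    assert recipe.status == "optimal"
    assert all(v == 0 for v in recipe.amounts.values())
    assert recipe.objective == 0


def test_forced_salt_held_at_exact_amount(catalog):
    spec = TargetSpec.paper_faithful(
        targets={"NH4+": 20, "NO3-": 40, "K+": 5.0, "Na+": 16.75},
        forced_salts={"NH4NO3": 18.25})
    problem = build_lp(spec, catalog)
    j = problem.salts.index("NH4NO3")
    assert problem.bounds[j] == (18.25, 18.25)
    recipe = solve(problem)
    assert recipe.status == "optimal"
    assert recipe.amounts["NH4NO3"] == 18.25


def test_unknown_forced_salt_rejected(catalog):
    spec = TargetSpec(targets={"K+": 1, "Cl-": 1}, forced_salts={"unobtainium": 1})
    with pytest.raises(CatalogError, match="unobtainium"):
        build_lp(spec, catalog)


def test_unreachable_ion_named(two_salt):
    with pytest.raises(UnreachableIonError, match="SO4 2-"):
        build_lp(TargetSpec(targets={"SO4 2-": 1.0}), two_salt)


def test_chloride_constrained_to_zero_is_infeasible(catalog):
    spec = TargetSpec(targets={"K+": 1.0, "Cl-": 0.0})
    recipe = solve(build_lp(spec, catalog.subset(["KCl"])))
    assert recipe.status == "infeasible"


def test_diagnose_reports_unit_imbalance(catalog):
    problem = build_lp(TargetSpec(targets={"K+": 1.0}),
                       catalog.subset(["KCl", "NaCl"]))
    report = diagnose_infeasibility(problem)
    lo, hi = report.imbalance_meq
    assert lo == pytest.approx(1.0)
    assert hi == pytest.approx(1.0)
    assert not report.has_charged_free
    assert "+1" in report.render()


def test_diagnose_soil_with_published_calcium(catalog):
    """Targeting the published soil Ca (12.4 mM) with nothing freed is
    unreachable by neutral salts: ~+20.3 meq/L of unmatched cation charge."""
    spec = soil_target_spec()
    targets = dict(spec.targets)
    targets["Ca2+"] = 12.4
    problem = build_lp(TargetSpec(targets=targets), soil_catalog(catalog))
    report = diagnose_infeasibility(problem)
    lo, hi = report.imbalance_meq
    assert lo <= 20.33 <= hi
    assert hi - lo < 0.1  # single-member pools here: nearly point estimate
    assert report.relaxed_recipe  # a least-infeasible suggestion is offered


def test_diagnose_refuses_feasible_problem(two_salt):
    problem = build_lp(TargetSpec(targets={"K+": 1.0, "Cl-": 1.0}), two_salt)
    with pytest.raises(ValueError, match="feasible"):
        diagnose_infeasibility(problem)


def test_soil_reconstruction_roundtrip(catalog):
    """The flagship end-to-end case: LP on the soil targets reproduces every
    constrained ion on deconstruction to < 0.1% relative."""
    spec = soil_target_spec()
    recipe = solve(build_lp(spec, soil_catalog(catalog)))
    assert recipe.status == "optimal"
    achieved = deconstruct(recipe, catalog)
    for ion, target in spec.targets.items():
        got = achieved.resolve(ion, catalog.registry)
        assert got == pytest.approx(target, rel=1e-3, abs=1e-9), ion
    # the published recipe optimum delivers calcium at the mass-balance level
    assert achieved["Ca2+"] == pytest.approx(SOIL_CA_MM, rel=1e-6)


def test_to_mg_per_l(catalog):
    mg = to_mg_per_l({"KNO3": 21.751}, catalog)
    assert mg["KNO3"] == pytest.approx(21.751 * 101.1023, rel=1e-6)
    assert mg["KNO3"] == pytest.approx(2199, rel=2e-4)  # published whole-mg value
    assert to_mg_per_l({"NaCl": 0.0}, catalog)["NaCl"] == 0.0
    mgcl = to_mg_per_l({"MgCl2.6H2O": 193.164 / catalog["MgCl2.6H2O"].molar_mass},
                       catalog)
    assert mgcl["MgCl2.6H2O"] == pytest.approx(193.164, abs=1e-9)
    with pytest.raises(CatalogError):
        to_mg_per_l({"bogus": 1.0}, catalog)


def test_solver_output_is_deterministic(catalog):
    spec = soil_target_spec()
    problem = build_lp(spec, soil_catalog(catalog))
    first = solve(problem).amounts
    for _ in range(3):
        assert solve(problem).amounts == first


def test_degenerate_optimum_breaks_ties_lexicographically(registry):
    """Two identical salts: all optima split 1 mM between them; the
    lexicographic rule must put everything on the later column being
    minimized last, i.e. pick the catalog-order-smallest vector (0 on the
    first? no: minimizing X1 first drives the first column to its minimum)."""
    from ionrecipe.catalog import catalog_from_dissociations
    cat = catalog_from_dissociations(
        {"KCl_a": {"K+": 1, "Cl-": 1}, "KCl_b": {"K+": 1, "Cl-": 1}}, registry)
    recipe = solve(build_lp(TargetSpec(targets={"K+": 1.0, "Cl-": 1.0}), cat))
    assert recipe.amounts["KCl_a"] == pytest.approx(0.0, abs=1e-9)
    assert recipe.amounts["KCl_b"] == pytest.approx(1.0, abs=1e-9)


def test_achieved_compositions_are_electroneutral(catalog, registry):
    """Neutral salt columns force sum(z*b)=0 on every recipe's ions."""
    for seed in range(5):
        problem = generate_synthetic_problem(seed, n_salts=7, n_ions=6)
        recipe = solve(build_lp(problem.targets, problem.catalog))
        assert recipe.status == "optimal"
        comp = deconstruct(recipe, problem.catalog)
        assert abs(charge_balance(comp, problem.catalog.registry)) < 1e-7
    spec = soil_target_spec()
    recipe = solve(build_lp(spec, soil_catalog(catalog)))
    comp = deconstruct(recipe, catalog)
    assert abs(charge_balance(comp, registry)) < 1e-9


def grid_optimum(A, b, c, step=0.01, tol=1e-9):
    """Brute-force LP oracle: enumerate recipes on a step grid, keep the
    cheapest satisfying A x = b."""
    bounds = [min(b[i] / A[i][j] for i in range(len(b)) if A[i][j])
              for j in range(len(c))]
    axes = [np.arange(0.0, ub + step / 2, step) for ub in bounds]
    best = None
    for x in itertools.product(*axes):
        if all(abs(sum(A[i][j] * x[j] for j in range(len(x))) - b[i]) < tol
               for i in range(len(b))):
            cost = sum(ci * xi for ci, xi in zip(c, x))
            if best is None or cost < best[0] - 1e-12:
                best = (cost, x)
    return best


@pytest.mark.parametrize("targets", [
    {"K+": 1.0, "Na+": 2.0, "Cl-": 3.0},
    {"K+": 2.0, "NO3-": 1.0, "Cl-": 1.0},
])
def test_lp_matches_grid_search_oracle(catalog, targets):
    salts = ["KCl", "NaCl", "KNO3", "NaNO3"]
    cat = catalog.subset(salts)
    problem = build_lp(TargetSpec(targets=targets), cat)
    recipe = solve(problem)
    assert recipe.status == "optimal"
    oracle = grid_optimum(problem.A.tolist(), problem.b.tolist(),
                          problem.c.tolist())
    assert oracle is not None
    assert recipe.objective == pytest.approx(oracle[0], abs=0.02)


def test_inequality_senses(two_salt):
    spec = TargetSpec(targets={"K+": 1.0, "Na+": 1.0, "Cl-": 3.0},
                      senses={"Cl-": "<="})
    recipe = solve(build_lp(spec, two_salt))
    assert recipe.status == "optimal"
    comp = deconstruct(recipe, two_salt)
    assert comp["Cl-"] <= 3.0 + 1e-9
    assert comp["K+"] == pytest.approx(1.0)
    spec_ge = TargetSpec(targets={"K+": 1.0, "Na+": 1.0, "Cl-": 2.5},
                         senses={"K+": ">=", "Na+": ">="})
    recipe = solve(build_lp(spec_ge, two_salt))
    assert recipe.status == "optimal"
    comp = deconstruct(recipe, two_salt)
    assert comp["K+"] >= 1.0 - 1e-9 and comp["Na+"] >= 1.0 - 1e-9
    assert comp["Cl-"] == pytest.approx(2.5)
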