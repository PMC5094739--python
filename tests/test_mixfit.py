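"""Scheffé mixture fitting, ANOVA partition, and the growth-data oracle."""

import numpy as np
import pytest

from ionrecipe.design import SingularDesignError
from ionrecipe.fixtures import load_growth_observations
from ionrecipe.mixfit import Observation, anova, fit_scheffe, response_trace


@pytest.fixture(scope="module")
def growth():
    df = load_growth_observations()
    # component 1 = K proportion, component 2 = Na proportion
    return [Observation((k, na), y)
            for k, na, y in zip(df["x_k"], df["x_na"], df["growth_pct"])]


@pytest.fixture(scope="module")
def growth_fit(growth):
    return fit_scheffe(growth, degree=2)


def test_exact_plane_is_fit_exactly():
    obs = [(x, 1 - x, 2 * x + 4 * (1 - x)) for x in (0.0, 0.25, 0.5, 1.0)]
    fit = fit_scheffe(obs, degree=2)
    assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-9)
    assert fit.coefficients["x2"] == pytest.approx(4.0, abs=1e-9)
    assert fit.coefficients["x1*x2"] == pytest.approx(0.0, abs=1e-8)
    assert float(fit.residuals @ fit.residuals) == pytest.approx(0.0, abs=1e-16)


def test_component_swap_symmetry(growth):
    fit = fit_scheffe(growth, degree=2)
    swapped = fit_scheffe([Observation(o.blend[::-1], o.response)
                           for o in growth], degree=2)
    assert swapped.coefficients["x1"] == pytest.approx(fit.coefficients["x2"])
    assert swapped.coefficients["x2"] == pytest.approx(fit.coefficients["x1"])
    assert swapped.coefficients["x1*x2"] == pytest.approx(
        fit.coefficients["x1*x2"])


def test_growth_coefficients_match_published(growth_fit):
    # printed as integers: 1011 (K vertex), 251 (Na vertex), 2112 (blending)
    assert growth_fit.coefficients["x1"] == pytest.approx(1011, abs=1)
    assert growth_fit.coefficients["x2"] == pytest.approx(251, abs=1)
    assert growth_fit.coefficients["x1*x2"] == pytest.approx(2112, abs=1)


def test_growth_anova_matches_published(growth_fit):
    table = anova(growth_fit)
    assert [(r.source, r.df) for r in table.rows] == [
        ("Model", 2), ("Linear mixture", 1), ("Quadratic", 1),
        ("Residual", 10), ("Lack of Fit", 2), ("Pure Error", 8),
        ("Cor Total", 12)]
    assert table["Model"].ss == pytest.approx(1.70e6, rel=5e-3)
    assert table["Model"].f == pytest.approx(45, abs=0.5)
    assert table["Linear mixture"].ss == pytest.approx(1.01e6, rel=5e-3)
    assert table["Quadratic"].ss == pytest.approx(6.92e5, rel=5e-3)
    assert table["Quadratic"].f == pytest.approx(37, abs=0.5)
    assert table["Lack of Fit"].ss == pytest.approx(6.53e4, rel=5e-3)
    assert table["Lack of Fit"].f == pytest.approx(2.14, abs=0.005)
    assert table["Lack of Fit"].p == pytest.approx(0.1804, abs=5e-4)
    assert table["Pure Error"].ss == pytest.approx(1.22e5, rel=5e-3)
    assert table["Quadratic"].p == pytest.approx(0.0001, abs=5e-5)
    assert table["Model"].p < 1e-4


def test_growth_fit_agrees_with_statsmodels_oracle(growth):
    """Independent no-intercept OLS on the expanded design matrix."""
    import statsmodels.api as sm

    from ionrecipe.design import scheffe_matrix

    X = scheffe_matrix([o.blend for o in growth], degree=2)
    y = [o.response for o in growth]
    res = sm.OLS(y, X).fit()
    fit = fit_scheffe(growth, degree=2)
    np.testing.assert_allclose(fit.coef_vector, res.params, rtol=1e-10)
    np.testing.assert_allclose(
        float(fit.residuals @ fit.residuals), res.ssr, rtol=1e-10)


def test_anova_renders_display_conventions(growth_fit):
    text = anova(growth_fit).render()
    assert "<0.0001" in text          # tiny p-values print as a bound
    assert "Lack of Fit" in text and "0.180" in text


@pytest.mark.parametrize("seed", range(4))
def test_partition_identities_on_random_data(seed):
    rng = np.random.default_rng(seed)
    blends = [(x, 1 - x) for x in rng.choice([0, 0.25, 0.5, 0.75, 1], size=14)]
    obs = [(*b, float(rng.normal(100 * b[0] + 40 * b[1], 5))) for b in blends]
    fit = fit_scheffe(obs, degree=2)
    table = anova(fit)
    ss = {r.source: r.ss for r in table.rows}
    df = {r.source: r.df for r in table.rows}
    assert ss["Model"] + ss["Residual"] == pytest.approx(ss["Cor Total"], rel=1e-6)
    assert ss["Linear mixture"] + ss["Quadratic"] == pytest.approx(
        ss["Model"], rel=1e-6, abs=1e-9)
    assert ss["Lack of Fit"] + ss["Pure Error"] == pytest.approx(
        ss["Residual"], rel=1e-6, abs=1e-9)
    assert df["Model"] + df["Residual"] == df["Cor Total"]
    assert df["Lack of Fit"] + df["Pure Error"] == df["Residual"]
    assert all(r.ss >= -1e-9 for r in table.rows)


def test_pure_error_invariant_to_model(growth):
    from ionrecipe.mixfit import _pure_error
    ss2, df2 = _pure_error(growth)
    fit1 = fit_scheffe(growth, degree=1)
    t1, t2 = anova(fit1), anova(fit_scheffe(growth, degree=2))
    assert t1["Pure Error"].ss == pytest.approx(ss2) == t2["Pure Error"].ss
    assert t1["Pure Error"].df == df2 == t2["Pure Error"].df


def test_coefficient_estimates_unbiased():
    """Parameter recovery: on data simulated from a known quadratic with iid
    noise, the mean estimate over many replicates approaches the truth."""
    rng = np.random.default_rng(7)
    truth = np.array([1011.0, 251.0, 2112.0])
    blends = [(1, 0)] * 3 + [(0.75, 0.25)] * 2 + [(0.5, 0.5)] * 3 + \
             [(0.25, 0.75)] * 2 + [(0, 1)] * 3
    from ionrecipe.design import scheffe_matrix
    X = scheffe_matrix(blends, degree=2)
    sigma = 120.0
    estimates = np.empty((1000, 3))
    for i in range(1000):
        y = X @ truth + rng.normal(0, sigma, size=len(blends))
        estimates[i] = np.linalg.lstsq(X, y, rcond=None)[0]
    se = sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)) / 1000)
    assert np.all(np.abs(estimates.mean(axis=0) - truth) < 4 * se)


def test_response_trace_endpoints_equal_vertex_coefficients(growth_fit):
    trace = response_trace(growth_fit, resolution=5)
    assert trace["predicted"].iloc[-1] == pytest.approx(
        growth_fit.coefficients["x1"])  # x1 = 1 endpoint
    assert trace["predicted"].iloc[0] == pytest.approx(
        growth_fit.coefficients["x2"])
    b = growth_fit.coefficients
    assert growth_fit.predict([(0.5, 0.5)])[0] == pytest.approx(
        0.5 * b["x1"] + 0.5 * b["x2"] + 0.25 * b["x1*x2"])


def test_midpoint_prediction_example():
    fit = fit_scheffe([(1, 0, 251.2), (0, 1, 1010.6),
                       (0.5, 0.5, 0.5 * 251.2 + 0.5 * 1010.6 + 0.25 * 2112.3)],
                      degree=2)
    assert fit.predict([(0.5, 0.5)])[0] == pytest.approx(1158.98, abs=0.05)


def test_zero_residual_reports_undefined_f():
    obs = [(x, 1 - x, 2 * x + 4 * (1 - x)) for x in (0.0, 0.0, 0.5, 1.0, 1.0)]
    table = anova(fit_scheffe(obs, degree=2))
    assert table["Residual"].ss == pytest.approx(0.0, abs=1e-18)
    assert table["Lack of Fit"].f is None
    assert any("undefined" in n for n in table.notes)


def test_no_replicates_omits_lof_lines():
    obs = [(x, 1 - x, float(i)) for i, x in enumerate((0.0, 0.3, 0.5, 1.0))]
    table = anova(fit_scheffe(obs, degree=2))
    sources = [r.source for r in table.rows]
    assert "Lack of Fit" not in sources and "Pure Error" not in sources
    assert any("no replicated blends" in n for n in table.notes)


def test_singular_design_names_term():
    obs = [(0.5, 0.5, 1.0), (0.5, 0.5, 2.0), (0.5, 0.5, 3.0)]
    with pytest.raises(SingularDesignError, match="x2"):
        fit_scheffe(obs, degree=2)


def test_rejects_nonfinite_response():
    with pytest.raises(ValueError):
        Observation((0.5, 0.5), float("nan"))
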