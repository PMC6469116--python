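import numpy as np
import pytest

from spikecontam import (
    AnalysisConfig,
    build_report,
    classify,
    estimate_sample_mass,
    fit_taxon,
    simulate,
)
from spikecontam.model import (
    REASON_CLASSIFIED,
    REASON_R2,
    REASON_SLOPE,
    DegenerateDesignError,
)
from spikecontam.simulate import ScenarioConfig


def test_perfect_inverse_fit():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    fit = fit_taxon(x, -x + 3, min_obs=4)
    assert fit.slope == pytest.approx(-1.0)
    assert fit.intercept == pytest.approx(3.0)
    assert fit.adj_r2 == pytest.approx(1.0)
    assert np.allclose(fit.residuals, 0.0, atol=1e-12)
    assert fit.p_slope == 0.0


def test_constant_response_has_nonpositive_adjusted_r2():
    x = np.arange(6.0)
    fit = fit_taxon(x, np.full(6, 2.0))
    assert fit.slope == pytest.approx(0.0)
    assert fit.adj_r2 <= 0.0


def test_fit_matches_extended_precision_normal_equations():
    """Closed-form oracle: normal equations evaluated in long double."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=10)
    y = -1.2 * x + 0.4 + rng.normal(scale=0.3, size=10)
    fit = fit_taxon(x, y, min_obs=6)

    xl, yl = x.astype(np.longdouble), y.astype(np.longdouble)
    n = xl.size
    sx, sy = xl.sum(), yl.sum()
    sxx, sxy = (xl * xl).sum(), (xl * yl).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = yl - intercept - slope * xl
    sse = float((resid * resid).sum())
    sst = float(((yl - yl.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst

    assert fit.slope == pytest.approx(float(slope), abs=1e-10)
    assert fit.intercept == pytest.approx(float(intercept), abs=1e-10)
    assert fit.r2 == pytest.approx(r2, abs=1e-10)
    assert fit.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - 2), abs=1e-10)


def test_fit_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    x = rng.uniform(0, 3, size=20)
    y = -x + 0.5 + rng.normal(scale=0.2, size=20)
    fit = fit_taxon(x, y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    assert fit.slope == pytest.approx(res.params[1], abs=1e-10)
    assert fit.intercept == pytest.approx(res.params[0], abs=1e-10)
    assert fit.adj_r2 == pytest.approx(res.rsquared_adj, abs=1e-10)
    assert fit.p_slope == pytest.approx(res.pvalues[1], rel=1e-8)
    assert np.allclose(fit.leverages, res.get_influence().hat_matrix_diag, atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_residuals_and_leverages_satisfy_ols_identities(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    fit = fit_taxon(x, y)
    assert abs(fit.residuals.sum()) < 1e-9
    assert abs(fit.leverages.sum() - 2.0) < 1e-9
    assert ((fit.leverages > 0) & (fit.leverages < 1)).all()


def test_fit_input_contracts():
    with pytest.raises(ValueError, match="min_obs"):
        fit_taxon([1, 2, 3], [1, 2, 3], min_obs=6)
    with pytest.raises(DegenerateDesignError):
        fit_taxon(np.ones(6), np.arange(6.0))
    with pytest.raises(ValueError, match="finite"):
        fit_taxon([1, 2, 3, 4, 5, np.nan], np.arange(6.0))


@pytest.mark.parametrize(
    "slope, adj_r2, expect, reason",
    [
        (-0.97, 0.95, True, REASON_CLASSIFIED),
        (+0.90, 0.95, False, REASON_SLOPE),
        (-0.90, 0.69, False, REASON_R2),
        (-0.90, 0.70, True, REASON_CLASSIFIED),  # boundary is inclusive
    ],
)
def test_classification_rule(slope, adj_r2, expect, reason):
    fit = fit_taxon(np.arange(6.0), np.arange(6.0))  # placeholder geometry
    fit.slope, fit.adj_r2 = slope, adj_r2
    call = classify(fit, r2_threshold=0.7)
    assert call.is_contaminant is expect
    assert call.reason == reason


def test_positive_slope_can_classify_when_sign_rule_is_off():
    fit = fit_taxon(np.arange(6.0), np.arange(6.0))
    fit.slope, fit.adj_r2 = 0.9, 0.95
    assert classify(fit, require_negative_slope=False).is_contaminant


@pytest.fixture(scope="module")
def dilution_report(mix_module):
    table, meta, truth = simulate(ScenarioConfig(seed=2))
    sm = estimate_sample_mass(table, mix_module, meta)
    return table, truth, build_report(table, mix_module, sm, AnalysisConfig())


@pytest.fixture(scope="module")
def mix_module():
    from spikecontam import load_ercc_reference

    return load_ercc_reference("bundled")


def test_host_taxon_is_never_called_a_contaminant(dilution_report):
    """The host tracks its own mass (positive slope): real signal."""
    _, truth, report = dilution_report
    host_calls = [c for c in report.calls if c.taxon_id == truth.host_taxon]
    assert host_calls and not host_calls[0].is_contaminant
    host_fit = [f for f in report.fits if f.taxon_id == truth.host_taxon][0]
    assert host_fit.slope > 0


def test_report_totals_are_additive_per_sample(dilution_report):
    _, _, report = dilution_report
    for s, total in report.total_mass_per_sample_ag.items():
        parts = sum(q.per_sample_mass_ag.get(s, 0.0) for q in report.masses)
        assert total == pytest.approx(parts, abs=1e-12)
    assert set(q.taxon_id for q in report.masses) == set(report.contaminant_ids)


def test_bh_adjustment_spans_fitted_taxa(dilution_report):
    _, _, report = dilution_report
    ps = [f.p_slope for f in report.fits]
    qs = [f.p_adj for f in report.fits]
    assert all(q is not None and q >= p - 1e-15 for p, q in zip(ps, qs))
    assert max(qs) <= 1.0


def test_classification_is_invariant_to_sample_order(mix_module):
    cfg = ScenarioConfig(n_masses=8, replicates=2, depth_mean=500_000, seed=9)
    table, meta, _ = simulate(cfg)
    sm = estimate_sample_mass(table, mix_module, meta)
    report = build_report(table, mix_module, sm, AnalysisConfig())

    rng = np.random.default_rng(0)
    perm = rng.permutation(table.n_samples)
    from spikecontam import CountTable

    shuffled = CountTable(
        table.taxa,
        [table.samples[j] for j in perm],
        table.counts[:, perm],
        table.is_spike,
    )
    sm2 = estimate_sample_mass(shuffled, mix_module, meta)
    report2 = build_report(shuffled, mix_module, sm2, AnalysisConfig())

    calls1 = {c.taxon_id: (c.is_contaminant, c.reason) for c in report.calls}
    calls2 = {c.taxon_id: (c.is_contaminant, c.reason) for c in report2.calls}
    assert calls1 == calls2
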