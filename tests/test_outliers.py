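import numpy as np
import pytest

from spikecontam import (
    CountTable,
    ErccMix,
    ErccTranscript,
    fit_taxon,
    flag_outliers,
    iterate_refit,
    studentized_residuals,
)

MIX = ErccMix((ErccTranscript("ERCC-00001", 1000, 1.0),), spike_mass_pg=25.0)


def _loo_oracle(x, y):
    """Literal leave-one-out refits: residual of point i against the fit
    without point i, scaled by that fit's prediction SE at x_i."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        b = ((xi - xi.mean()) * (yi - yi.mean())).sum() / ((xi - xi.mean()) ** 2).sum()
        a = yi.mean() - b * xi.mean()
        resid = yi - a - b * xi
        s2 = (resid**2).sum() / (n - 3)
        sxx = ((xi - xi.mean()) ** 2).sum()
        pred_var = s2 * (1 + 1 / (n - 1) + (x[i] - xi.mean()) ** 2 / sxx)
        out[i] = (y[i] - a - b * x[i]) / np.sqrt(pred_var)
    return out


def test_perfect_fit_has_all_zero_studentized_residuals():
    x = np.arange(8.0)
    fit = fit_taxon(x, -x + 3)
    assert np.all(studentized_residuals(fit) == 0.0)


@pytest.mark.parametrize("n, seed", [(10, 11), (50, 1), (200, 2)])
def test_studentized_residuals_match_literal_loo_refits(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 3, size=n)
    y = -x + rng.normal(scale=0.5, size=n)
    fit = fit_taxon(x, y)
    assert np.allclose(studentized_residuals(fit), _loo_oracle(x, y), atol=1e-9)


def test_studentized_residuals_match_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    x = rng.uniform(0, 3, size=30)
    y = -x + rng.normal(scale=0.4, size=30)
    fit = fit_taxon(x, y)
    infl = sm.OLS(y, sm.add_constant(x)).fit().get_influence()
    assert np.allclose(
        studentized_residuals(fit), infl.resid_studentized_external, atol=1e-9
    )


def _table_for(fit_y_counts, ercc=1000):
    """One spike row + one taxon row across len(counts) samples."""
    counts = np.array([[ercc] * len(fit_y_counts), list(fit_y_counts)])
    return CountTable(
        ["ERCC-00001", "Taxon"],
        [f"S{j}" for j in range(len(fit_y_counts))],
        counts.astype(np.int64),
        np.array([True, False]),
    )


def _fit_from_table(table, masses, pseudocount=0.5):
    r = (table.counts[1] + pseudocount) / table.total_reads * 1e6
    return fit_taxon(
        np.log10(masses), np.log10(r),
        sample_ids=table.samples, taxon_id="Taxon",
    )


def test_one_sided_flagging_ignores_depletion():
    rng = np.random.default_rng(5)
    masses = np.logspace(0, 3, 20)
    lam = 4000 / masses
    counts = rng.poisson(lam)
    counts[4] = int(lam[4] * 30)   # gross excess
    counts[10] = 0                 # gross depletion
    table = _table_for(counts, ercc=50_000)
    fit = _fit_from_table(table, masses)
    calls = {c.sample_id: c for c in flag_outliers(fit, table, MIX)}
    assert calls["S4"].is_outlier
    assert not calls["S10"].is_outlier  # low side not flagged one-sided
    two_sided = {
        c.sample_id: c
        for c in flag_outliers(fit, table, MIX, one_sided=False)
    }
    assert two_sided["S10"].studentized_residual < 0


def test_flag_threshold_behaviour_and_pvalues():
    rng = np.random.default_rng(8)
    masses = np.logspace(0, 3, 30)
    counts = rng.poisson(2000 / masses)
    table = _table_for(counts, ercc=20_000)
    fit = _fit_from_table(table, masses)
    calls = flag_outliers(fit, table, MIX, flag_threshold=2.0)
    t = studentized_residuals(fit)
    for c, ti in zip(calls, t):
        assert c.is_outlier == (ti > 2.0)
        assert 0.0 <= c.p_value <= 1.0
        assert c.p_bonferroni >= c.p_value
        assert c.excess_reads >= 0.0


def test_excess_partition_identity():
    """excess mass + expected-contamination mass = observed mass for
    flagged samples (all masses through the same spike ratio)."""
    rng = np.random.default_rng(5)
    masses = np.logspace(0, 3, 20)
    counts = rng.poisson(4000 / masses)
    counts[3] = int(4000 / masses[3] * 20)
    table = _table_for(counts, ercc=50_000)
    fit = _fit_from_table(table, masses)
    for c in flag_outliers(fit, table, MIX):
        if not c.is_outlier:
            continue
        j = table.sample_pos(c.sample_id)
        scale = MIX.spike_mass_pg * 1e6 / table.ercc_reads[j]
        observed_mass = scale * c.observed_reads
        expected_mass = scale * c.expected_reads
        assert c.excess_mass_ag + expected_mass == pytest.approx(
            observed_mass, rel=1e-9
        )


def test_iterate_refit_is_identity_on_clean_data():
    rng = np.random.default_rng(12)
    masses = np.logspace(0, 3, 24)
    counts = rng.poisson(3000 / masses)
    table = _table_for(counts, ercc=30_000)
    fit = _fit_from_table(table, masses)
    if any(c.is_outlier for c in flag_outliers(fit, table, MIX, flag_threshold=8.0)):
        pytest.fail("fixture unexpectedly contains a gross outlier")
    refit, _ = iterate_refit(fit, table, MIX, flag_threshold=8.0)
    assert refit.slope == fit.slope
    assert refit.included_samples == fit.included_samples


def test_iterate_refit_excludes_gross_outlier_and_matches_clean_fit():
    rng = np.random.default_rng(12)
    masses = np.logspace(0, 3, 24)
    clean = rng.poisson(3000 / masses)
    spiked = clean.copy()
    spiked[7] = int(3000 / masses[7] * 40)
    table = _table_for(spiked, ercc=30_000)
    fit = _fit_from_table(table, masses)
    refit, calls = iterate_refit(fit, table, MIX)

    assert any(c.sample_id == "S7" and c.is_outlier for c in calls)
    assert "S7" not in refit.included_samples
    keep = [s for s in fit.included_samples if s in refit.included_samples]
    idx = [fit.included_samples.index(s) for s in keep]
    manual = fit_taxon(fit.x[idx], fit.y[idx], sample_ids=keep)
    assert refit.slope == pytest.approx(manual.slope, abs=1e-12)
    assert len(calls) == len(fit.included_samples)


def test_increasing_a_count_never_decreases_its_residual():
    rng = np.random.default_rng(4)
    masses = np.logspace(0, 3, 15)
    counts = rng.poisson(1500 / masses) + 1
    prev = -np.inf
    for boost in (0, 5, 50, 500):
        c = counts.copy()
        c[6] += boost
        table = _table_for(c, ercc=20_000)
        fit = _fit_from_table(table, masses)
        t6 = studentized_residuals(fit)[6]
        assert t6 >= prev - 1e-12
        prev = t6


def test_minimum_sample_guard():
    with pytest.raises(ValueError, match="n >= 4"):
        x = np.arange(3.0)
        fit = fit_taxon(x, -x, min_obs=3)
        studentized_residuals(fit)
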