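"""Studentized-residual outlier detection within contaminant regressions.

The contaminant regression predicts how many reads of a taxon each sample
should carry from contamination alone. A sample's deviation from that
prediction, divided by its leave-one-out standard error, is the
externally studentized residual: under the null of pure contamination it
follows a t distribution with n-3 degrees of freedom, so values beyond
about +2 mark samples carrying more of the organism than contamination
explains — candidate true infections. External (leave-one-out)
studentization is used so an extreme sample cannot inflate its own error
estimate; it also accounts for the varying leverage of samples along the
mass axis. Flagged samples have their reads partitioned into the expected
contamination component and the excess, and the excess is converted to
mass through the spike-in ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ercc import ErccMix
from .io_tables import CountTable
from .mass import PG_TO_AG
from .model import TaxonFit, fit_taxon

__all__ = [
    "OutlierCall",
    "studentized_residuals",
    "flag_outliers",
    "iterate_refit",
]

_LEVERAGE_TOL = 1e-12


@dataclass
class OutlierCall:
    """One (sample, taxon) residual test and its excess partition."""

    sample_id: str
    taxon_id: str
    studentized_residual: float
    p_value: float
    p_bonferroni: float
    is_outlier: bool
    observed_reads: int
    expected_reads: float
    excess_reads: float
    excess_mass_ag: float
    taxon_is_contaminant: bool = False


def studentized_residuals(fit: TaxonFit) -> np.ndarray:
    """Externally studentized residuals of a two-parameter OLS fit.

    Uses the leave-one-out identity
    s_(i)^2 = ((n-2) s^2 - e_i^2 / (1 - h_ii)) / (n-3),
    t_i = e_i / (s_(i) sqrt(1 - h_ii)),
    equivalent to literally refitting without observation i. Degenerate
    leverage (h_ii ~ 1) yields a signed infinity with a warning.
    """
    e = fit.residuals
    h = fit.leverages
    n = fit.n_obs
    if n < 4:
        raise ValueError("externally studentized residuals need n >= 4")
    sse = float((e**2).sum())
    if sse == 0.0:
        return np.zeros(n)

    t = np.empty(n)
    for i in range(n):
        if h[i] >= 1.0 - _LEVERAGE_TOL:
            warnings.warn(
                f"observation {fit.included_samples[i]}: leverage ~1, "
                "studentized residual undefined"
            )
            t[i] = np.sign(e[i]) * np.inf if e[i] != 0 else 0.0
            continue
        s2_loo = (sse - e[i] ** 2 / (1.0 - h[i])) / (n - 3)
        if s2_loo <= 0.0:
            # one observation carries essentially all the error
            t[i] = np.sign(e[i]) * np.inf if e[i] != 0 else 0.0
            continue
        t[i] = e[i] / np.sqrt(s2_loo * (1.0 - h[i]))
    return t


def flag_outliers(
    fit: TaxonFit,
    table: CountTable,
    mix: ErccMix,
    flag_threshold: float = 2.0,
    one_sided: bool = True,
    pseudocount: float | None = 0.5,
) -> list[OutlierCall]:
    """Residual tests for every sample in a taxon's fit.

    A sample is flagged when its studentized residual exceeds
    ``flag_threshold`` (high side only by default: excess, not
    depletion). Expected reads come from back-transforming the regression
    prediction at the sample's log mass (rpm prediction times total reads
    over 1e6, minus the fitting pseudocount when one was used); the
    excess over the expectation is converted to attograms through the
    spike ratio. The two-sided t(n-3) p-value is reported raw and
    Bonferroni-adjusted across the n comparisons within the taxon.
    """
    t_vals = studentized_residuals(fit)
    n = fit.n_obs
    counts = table.taxon_row(fit.taxon_id)
    totals = table.total_reads
    ercc = table.ercc_reads
    pc = pseudocount if pseudocount is not None else 0.0

    calls = []
    for i, sample in enumerate(fit.included_samples):
        j = table.sample_pos(sample)
        t_i = float(t_vals[i])
        if np.isfinite(t_i):
            p = float(2.0 * stats.t.sf(abs(t_i), df=n - 3))
        else:
            p = 0.0
        flagged = (t_i > flag_threshold) if one_sided else (abs(t_i) > flag_threshold)
        pred_rpm = 10.0 ** float(fit.predict(fit.x[i]))
        expected = max(pred_rpm * totals[j] / 1e6 - pc, 0.0)
        observed = int(counts[j])
        excess = max(observed - expected, 0.0)
        calls.append(
            OutlierCall(
                sample_id=sample,
                taxon_id=fit.taxon_id,
                studentized_residual=t_i,
                p_value=p,
                p_bonferroni=min(1.0, p * n),
                is_outlier=bool(flagged),
                observed_reads=observed,
                expected_reads=float(expected),
                excess_reads=float(excess),
                excess_mass_ag=float(
                    mix.spike_mass_pg * PG_TO_AG * excess / ercc[j]
                ),
            )
        )
    return calls


def iterate_refit(
    fit: TaxonFit,
    table: CountTable,
    mix: ErccMix,
    flag_threshold: float = 2.0,
    one_sided: bool = True,
    max_iter: int = 3,
    min_obs: int = 6,
    pseudocount: float | None = 0.5,
) -> tuple[TaxonFit, list[OutlierCall]]:
    """Alternate outlier flagging and refitting without flagged samples.

    Stops when a round adds no new flags, after ``max_iter`` rounds, or
    when a further exclusion would leave fewer than ``min_obs`` samples
    (with a warning). Returns the final fit plus one call per originally
    included sample: flagged samples keep the statistics from the round
    that flagged them, the rest are measured against the final fit.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    current = fit
    flagged_calls: dict[str, OutlierCall] = {}
    for _ in range(max_iter):
        calls = flag_outliers(
            current, table, mix, flag_threshold, one_sided, pseudocount
        )
        new = [c for c in calls if c.is_outlier and c.sample_id not in flagged_calls]
        if not new:
            break
        keep_ids = [
            s
            for s in current.included_samples
            if s not in flagged_calls and s not in {c.sample_id for c in new}
        ]
        if len(keep_ids) < min_obs:
            warnings.warn(
                f"{fit.taxon_id}: outlier exclusion would leave "
                f"{len(keep_ids)} < {min_obs} samples; stopping"
            )
            break
        for c in new:
            flagged_calls[c.sample_id] = c
        keep = np.array([s in set(keep_ids) for s in current.included_samples])
        current = fit_taxon(
            current.x[keep],
            current.y[keep],
            sample_ids=keep_ids,
            taxon_id=fit.taxon_id,
            min_obs=min_obs,
        )
        current.p_adj = fit.p_adj

    final_calls = flag_outliers(
        current, table, mix, flag_threshold, one_sided, pseudocount
    )
    merged = {c.sample_id: c for c in final_calls}
    merged.update(flagged_calls)
    ordered = [merged[s] for s in fit.included_samples if s in merged]
    return current, ordered
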