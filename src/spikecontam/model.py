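"""Per-taxon log-log regression and contaminant classification.

A reagent contaminant enters every library at a fixed absolute mass, so
its share of the reads — rpm — falls as sample input mass rises: on
log10-log10 axes, rpm versus input mass is linear with negative slope
(exactly -1 when the sample dominates the mass pool). Each non-spike
taxon is therefore fit by ordinary least squares of log10(rpm) on
log10(mass in pg), and called a contaminant when the fit is strong
(adjusted R-squared at or above threshold, 0.7 by default) and inverse
(negative slope). A strong *positive* association is the opposite
signature: a taxon tracking its sample, i.e. real signal.

The fit is computed closed-form (normal equations) rather than through a
regression library because its by-products — residuals, leverages, the
residual standard error — feed the studentized-residual outlier stage and
are part of the method's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .ercc import ErccMix
from .io_tables import CountTable, ValidationError
from .mass import (
    MassQuant,
    SampleMassEstimate,
    quantify_taxon_mass,
    rpm,
)

__all__ = [
    "DegenerateDesignError",
    "TaxonFit",
    "ContaminantCall",
    "ContaminantReport",
    "fit_taxon",
    "classify",
    "build_report",
]

REASON_CLASSIFIED = "classified"
REASON_R2 = "r2_below_threshold"
REASON_SLOPE = "slope_nonnegative"
REASON_OBS = "insufficient_obs"
REASON_PREVALENCE = "insufficient_prevalence"


class DegenerateDesignError(ValueError):
    """All x values identical; the slope is undefined."""


@dataclass
class TaxonFit:
    """One taxon's OLS fit of log10(rpm) on log10(input mass, pg).

    Slope is dimensionless (decades of rpm per decade of pg). Residual
    diagnostics (residuals, leverages, residual SE) are retained for the
    outlier stage. ``p_adj`` is filled in across taxa by the report
    builder (Benjamini-Hochberg).
    """

    taxon_id: str
    n_obs: int
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_slope: float
    residuals: np.ndarray
    leverages: np.ndarray
    residual_se: float
    included_samples: list[str]
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    p_adj: float | None = None

    def predict(self, log_mass: np.ndarray | float) -> np.ndarray | float:
        """Predicted log10(rpm) at the given log10 mass."""
        return self.intercept + self.slope * np.asarray(log_mass, dtype=float)


@dataclass
class ContaminantCall:
    taxon_id: str
    is_contaminant: bool
    reason: str

    def __post_init__(self) -> None:
        if self.is_contaminant and self.reason != REASON_CLASSIFIED:
            raise ValueError("contaminant call must carry reason 'classified'")


@dataclass
class ContaminantReport:
    """Everything the workflow concludes about one count table."""

    fits: list[TaxonFit]
    calls: list[ContaminantCall]
    masses: list[MassQuant]
    sample_masses: list[SampleMassEstimate]
    outliers: list  # list[OutlierCall]; typed loosely to avoid a cycle
    total_mass_per_sample_ag: dict[str, float]
    total_mass_mean_ag: float
    total_mass_sd_ag: float

    @property
    def contaminant_ids(self) -> list[str]:
        return [c.taxon_id for c in self.calls if c.is_contaminant]


def fit_taxon(
    log_mass: Sequence[float] | np.ndarray,
    log_rpm: Sequence[float] | np.ndarray,
    sample_ids: Sequence[str] | None = None,
    taxon_id: str = "",
    min_obs: int = 6,
) -> TaxonFit:
    """OLS with intercept of log10(rpm) on log10(mass).

    Returns slope, intercept, (adjusted) R-squared, the two-sided p-value
    of the slope (t statistic, n-2 df), residuals, hat-matrix leverages
    and the residual standard error sqrt(SSE/(n-2)).

    Raises ``ValueError`` for fewer than ``min_obs`` finite observations
    and ``DegenerateDesignError`` for a constant x.
    """
    x = np.asarray(log_mass, dtype=float)
    y = np.asarray(log_rpm, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log_mass and log_rpm must be 1-D of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    n = x.size
    if n < min_obs:
        raise ValueError(f"need at least min_obs={min_obs} observations, got {n}")
    if sample_ids is None:
        sample_ids = [f"obs{i}" for i in range(n)]
    sample_ids = list(sample_ids)
    if len(sample_ids) != n:
        raise ValueError("sample_ids length mismatch")

    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx <= 0.0:
        raise DegenerateDesignError("degenerate design: zero variance in x")
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (intercept + slope * x)
    sse = float((resid**2).sum())
    sst = float(((y - ybar) ** 2).sum())
    if sst > 0.0:
        r2 = 1.0 - sse / sst
    else:
        r2 = 0.0  # constant y: nothing to explain
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    residual_se = np.sqrt(sse / (n - 2))
    if residual_se > 0.0:
        t_stat = slope / (residual_se / np.sqrt(sxx))
        p_slope = float(2.0 * stats.t.sf(abs(t_stat), df=n - 2))
    else:
        p_slope = 0.0 if slope != 0.0 else 1.0

    leverages = 1.0 / n + (x - xbar) ** 2 / sxx
    return TaxonFit(
        taxon_id=taxon_id,
        n_obs=n,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        adj_r2=float(adj_r2),
        p_slope=p_slope,
        residuals=resid,
        leverages=leverages,
        residual_se=float(residual_se),
        included_samples=sample_ids,
        x=x,
        y=y,
    )


def classify(
    fit: TaxonFit,
    r2_threshold: float = 0.7,
    require_negative_slope: bool = True,
) -> ContaminantCall:
    """Contaminant call from a fit: inverse (slope < 0) and strong
    (adjusted R-squared >= threshold, boundary inclusive)."""
    if require_negative_slope and not fit.slope < 0.0:
        return ContaminantCall(fit.taxon_id, False, REASON_SLOPE)
    if not fit.adj_r2 >= r2_threshold:
        return ContaminantCall(fit.taxon_id, False, REASON_R2)
    return ContaminantCall(fit.taxon_id, True, REASON_CLASSIFIED)


def build_report(
    table: CountTable,
    mix: ErccMix,
    sample_masses: Sequence[SampleMassEstimate],
    config: AnalysisConfig | None = None,
) -> ContaminantReport:
    """Run fits, classification, outlier detection and mass quantification.

    Every non-spike taxon detected in at least ``min_prevalence`` of
    samples (and at least ``min_obs`` of them) is fitted; in pseudocount
    mode all samples enter each fit, otherwise only the samples where the
    taxon was detected. Classified contaminants get an outlier pass
    (flag / refit up to ``max_iter`` rounds) and a per-sample mass
    quantification over all samples, excluding flagged ones when outlier
    exclusion is on; unclassified-but-fitted taxa get a single outlier
    pass so that excess-over-contamination screening does not depend on
    the R-squared gate. Per-sample total contaminant mass sums the
    classified taxa.
    """
    from .outliers import flag_outliers, iterate_refit

    config = config or AnalysisConfig()
    by_id = {sm.sample_id: sm for sm in sample_masses}
    missing = [s for s in table.samples if s not in by_id]
    if missing:
        raise ValidationError(f"no mass estimate for sample(s): {', '.join(missing[:5])}")
    log_mass = np.log10([by_id[s].mass_pg for s in table.samples])

    pc = config.pseudocount
    rpm_fit = rpm(table, pseudocount=pc if pc is not None else 0.0)

    fits: list[TaxonFit] = []
    calls: list[ContaminantCall] = []
    n_samples = table.n_samples
    for i, taxon in enumerate(table.taxa):
        if table.is_spike[i]:
            continue
        detected = table.counts[i] > 0
        n_det = int(detected.sum())
        if n_det < config.min_obs:
            calls.append(ContaminantCall(taxon, False, REASON_OBS))
            continue
        if n_det / n_samples < config.min_prevalence:
            calls.append(ContaminantCall(taxon, False, REASON_PREVALENCE))
            continue
        if pc is not None:
            sel = np.ones(n_samples, dtype=bool)
        else:
            sel = detected
        try:
            fit = fit_taxon(
                log_mass[sel],
                np.log10(rpm_fit[i][sel]),
                sample_ids=[s for s, keep in zip(table.samples, sel) if keep],
                taxon_id=taxon,
                min_obs=config.min_obs,
            )
        except DegenerateDesignError:
            warnings.warn(f"{taxon}: degenerate design, skipping fit")
            calls.append(ContaminantCall(taxon, False, REASON_OBS))
            continue
        fits.append(fit)
        calls.append(
            classify(fit, config.r2_threshold, config.require_negative_slope)
        )

    # BH adjustment of the slope p-values across all fitted taxa (reported
    # for filtering; classification itself uses the R^2 + sign rule only).
    if fits:
        p_adj = stats.false_discovery_control(
            [f.p_slope for f in fits], method="bh"
        )
        for f, p in zip(fits, p_adj):
            f.p_adj = float(p)

    contaminants = {c.taxon_id for c in calls if c.is_contaminant}
    outlier_calls = []
    excluded: dict[str, set[str]] = {}
    for fit in fits:
        if fit.taxon_id in contaminants:
            refit, taxon_calls = iterate_refit(
                fit,
                table,
                mix,
                flag_threshold=config.flag_threshold,
                one_sided=config.one_sided,
                max_iter=config.max_iter,
                min_obs=config.min_obs,
                pseudocount=pc,
            )
            excluded[fit.taxon_id] = {
                oc.sample_id for oc in taxon_calls if oc.is_outlier
            }
        else:
            taxon_calls = flag_outliers(
                fit,
                table,
                mix,
                flag_threshold=config.flag_threshold,
                one_sided=config.one_sided,
                pseudocount=pc,
            )
        for oc in taxon_calls:
            oc.taxon_is_contaminant = fit.taxon_id in contaminants
        outlier_calls.extend(taxon_calls)

    masses: list[MassQuant] = []
    for call in calls:
        if not call.is_contaminant:
            continue
        include = [
            s
            for s in table.samples
            if not (config.outlier_exclusion and s in excluded.get(call.taxon_id, ()))
        ]
        masses.append(quantify_taxon_mass(table, call.taxon_id, mix, include))

    totals = {s: 0.0 for s in table.samples}
    for q in masses:
        for s, m in q.per_sample_mass_ag.items():
            totals[s] += m
    values = np.array(list(totals.values()), dtype=float)
    total_mean = float(values.mean()) if values.size else 0.0
    total_sd = float(values.std(ddof=1)) if values.size > 1 else 0.0

    if not any(c.is_contaminant for c in calls) and not fits:
        warnings.warn("no taxa passed the prevalence filter; empty report")

    return ContaminantReport(
        fits=fits,
        calls=calls,
        masses=masses,
        sample_masses=list(sample_masses),
        outliers=outlier_calls,
        total_mass_per_sample_ag=totals,
        total_mass_mean_ag=total_mean,
        total_mass_sd_ag=total_sd,
    )
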