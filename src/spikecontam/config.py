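"""Analysis configuration with the package-wide defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    """Tunable parameters of the contamination workflow.

    Attributes
    ----------
    spike_mass_pg
        Total spike-in mass added to every library, picograms.
    spike_prefix
        Taxon-ID prefix marking spike-in rows in the count table.
    mass_mode
        ``given`` uses metadata masses, ``inferred`` derives each sample's
        mass from its spike-in read share, ``auto`` prefers given and falls
        back to inferred.
    min_ercc_reads
        Minimum spike reads required for mass inference; below this the
        spike/sample read ratio is too unstable to invert.
    r2_threshold
        Adjusted R-squared at or above which a taxon's inverse log-log fit
        is called contamination.
    require_negative_slope
        Demand a negative slope in addition to the R-squared rule. A strong
        fit with positive slope is mass-tracking (real) signal.
    min_prevalence
        Fraction of samples in which a taxon must be detected (>=1 read)
        before it is fitted at all.
    min_obs
        Minimum observations entering a regression.
    pseudocount
        Reads added to every cell before rpm for fitting, so that
        non-detections stay in the regression; ``None`` switches to
        excluding zero-count samples from each taxon's fit. In the sparse
        count regime the inverse-linear signature lives largely in the
        zeros, so the pseudocount mode is the default.
    flag_threshold
        Studentized-residual cutoff for outlier flagging.
    one_sided
        Flag only the high side (excess over contamination); low-side
        deviations are depletion, not infection.
    outlier_exclusion
        Exclude flagged samples from contaminant mass summaries.
    max_iter
        Maximum flag-and-refit rounds per taxon.
    seed
        Seed recorded in run metadata (analysis itself is deterministic).
    """

    spike_mass_pg: float = 25.0
    spike_prefix: str = "ERCC-"
    mass_mode: str = "auto"
    min_ercc_reads: int = 100
    r2_threshold: float = 0.7
    require_negative_slope: bool = True
    min_prevalence: float = 0.25
    min_obs: int = 6
    pseudocount: float | None = 0.5
    flag_threshold: float = 2.0
    one_sided: bool = True
    outlier_exclusion: bool = True
    max_iter: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_mode not in ("auto", "given", "inferred"):
            raise ValueError(f"unknown mass_mode {self.mass_mode!r}")
        if self.spike_mass_pg <= 0:
            raise ValueError("spike_mass_pg must be positive")
        if self.min_obs < 3:
            raise ValueError("min_obs must be at least 3")
        if self.pseudocount is not None and self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive or None")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
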