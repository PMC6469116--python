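"""Reads-per-million normalization and spike-anchored mass estimation.

The mass-ratio equation is the quantitative core of the workflow: because
every library carries the same known spike mass, read counts convert to
absolute mass by

    mass(X, s) = spike_mass * reads(X, s) / spike_reads(s)

for any read category X in sample s. Applied to a taxon it yields the
taxon's absolute mass per library (reported in attograms, 1 pg = 1e6 ag);
applied to all non-spike reads it yields the sample's own input mass,
which is how picogram-level inputs can be measured from sequencing alone.
The per-sample read denominator cancels in the ratio, so using rpm values
in place of raw counts gives identical masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ercc import ErccMix
from .io_tables import CountTable, SampleMeta, ValidationError

__all__ = [
    "PG_TO_AG",
    "SampleMassEstimate",
    "MassQuant",
    "rpm",
    "estimate_sample_mass",
    "quantify_taxon_mass",
]

PG_TO_AG = 1e6


@dataclass
class SampleMassEstimate:
    """One sample's input mass (picograms) and where it came from."""

    sample_id: str
    mass_pg: float
    source: str  # "given" | "inferred"
    ercc_reads: int
    nonspike_reads: int

    def __post_init__(self) -> None:
        if self.mass_pg <= 0:
            raise ValidationError(f"sample {self.sample_id}: mass must be positive")
        if self.source not in ("given", "inferred"):
            raise ValidationError(f"sample {self.sample_id}: bad source {self.source!r}")


@dataclass
class MassQuant:
    """Per-sample absolute mass of one taxon, attograms, with mean +/- SD."""

    taxon_id: str
    per_sample_mass_ag: dict[str, float]
    mean_mass_ag: float
    sd_mass_ag: float


def rpm(table: CountTable, pseudocount: float = 0.0) -> np.ndarray:
    """Reads per million of each sample's total (spike + non-spike) reads.

    ``pseudocount`` adds a constant to every cell's numerator before
    normalizing (the denominator stays the raw total), keeping
    non-detections finite on the log scale for regression.
    """
    totals = table.total_reads.astype(float)
    return (table.counts + pseudocount) / totals * 1e6


def estimate_sample_mass(
    table: CountTable,
    mix: ErccMix,
    meta: Sequence[SampleMeta] | None = None,
    mode: str = "auto",
    min_ercc_reads: int = 100,
) -> list[SampleMassEstimate]:
    """Per-sample input mass, from metadata and/or the spike-in ratio.

    Inferred mode solves the mass-ratio equation with the whole sample in
    place of the contaminant: mass = spike_mass * nonspike_reads /
    spike_reads. Host reads dominate the non-spike numerator, which is the
    point — the sample's mass axis is its total (mostly host) input.
    """
    if mode not in ("auto", "given", "inferred"):
        raise ValidationError(f"unknown mass mode {mode!r}")
    by_id = {m.sample_id: m for m in (meta or [])}
    ercc = table.ercc_reads
    nonspike = table.nonspike_reads

    out = []
    for j, sample in enumerate(table.samples):
        given = by_id.get(sample)
        given_mass = None if given is None else given.input_mass_pg
        use_given = mode == "given" or (mode == "auto" and given_mass is not None)
        if use_given:
            if given_mass is None:
                raise ValidationError(
                    f"mass_mode=given but sample {sample} has no input_mass_pg"
                )
            out.append(
                SampleMassEstimate(sample, float(given_mass), "given",
                                   int(ercc[j]), int(nonspike[j]))
            )
            continue
        if ercc[j] < min_ercc_reads:
            detail = (
                "no metadata mass and too few spike reads to infer"
                if mode == "auto"
                else "too few spike reads to infer mass"
            )
            raise ValidationError(
                f"sample {sample}: {detail} ({int(ercc[j])} < {min_ercc_reads})"
            )
        mass = mix.spike_mass_pg * nonspike[j] / ercc[j]
        out.append(
            SampleMassEstimate(sample, float(mass), "inferred",
                               int(ercc[j]), int(nonspike[j]))
        )
    return out


def quantify_taxon_mass(
    table: CountTable,
    taxon_id: str,
    mix: ErccMix,
    include_samples: Iterable[str] | None = None,
) -> MassQuant:
    """Absolute mass of one taxon in each included sample, attograms.

    Solves mass = spike_mass * taxon_reads / spike_reads per sample; the
    mean and the n-1 (sample) SD are taken over the included samples only.
    A zero count is a zero mass, not a missing value.
    """
    counts = table.taxon_row(taxon_id)
    idx = table.taxa.index(taxon_id)
    if table.is_spike[idx]:
        raise ValidationError(f"taxon {taxon_id} is a spike-in row")
    if include_samples is None:
        include = list(table.samples)
    else:
        include = list(include_samples)
    if not include:
        raise ValidationError("empty include_samples set")

    ercc = table.ercc_reads
    per: dict[str, float] = {}
    for sample in include:
        j = table.sample_pos(sample)
        if ercc[j] <= 0:
            raise ValidationError(f"sample {sample}: zero spike reads")
        per[sample] = mix.spike_mass_pg * PG_TO_AG * counts[j] / ercc[j]

    values = np.array(list(per.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return MassQuant(taxon_id, per, mean, sd)
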