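"""ERCC spike-in mix reference.

The workflow's absolute-quantification anchor is a panel of 92 synthetic
RNA transcripts (the ERCC set) added to every library at a known total
mass, 25 pg by default. Only two things about the panel matter downstream:
its total spiked mass (for the mass-ratio equation) and each transcript's
share of that mass (for allocating simulated spike reads among the 92
rows). The mass share of a transcript is proportional to concentration
times length, since mass per molecule scales with transcript length.

The bundled reference sheet is a synthetic stand-in: the commercial mix's
per-transcript concentration table is not reproduced here (and the
concentration *range* as printed in the source experiment contains an
obvious exponent typo), so the bundled sheet uses 92 transcripts with
log-spaced concentrations spanning six decades and representative lengths.
Any user sheet with the same three columns can be substituted; the method
itself only ever uses the total spike mass and total spike reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["ErccTranscript", "ErccMix", "load_ercc_reference", "mass_fractions"]

DEFAULT_SPIKE_MASS_PG = 25.0


@dataclass(frozen=True)
class ErccTranscript:
    """One spike-in transcript: identity, length (nt), relative concentration."""

    transcript_id: str
    length_nt: int
    concentration: float
    mix_label: str = "Mix1"

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"{self.transcript_id}: length_nt must be positive")
        if self.concentration <= 0:
            raise ValueError(f"{self.transcript_id}: concentration must be positive")


@dataclass
class ErccMix:
    """A spike-in panel and the total mass of it added per library.

    Concentrations are in arbitrary molar units; only within-mix ratios
    enter any computation, so the mix is invariant to rescaling all
    concentrations by a positive constant.
    """

    transcripts: tuple[ErccTranscript, ...]
    spike_mass_pg: float = DEFAULT_SPIKE_MASS_PG
    _fractions: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("ErccMix requires at least one transcript")
        if self.spike_mass_pg <= 0:
            raise ValueError("spike_mass_pg must be positive")
        ids = [t.transcript_id for t in self.transcripts]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate transcript ids: {', '.join(dupes)}")
        weights = [t.concentration * t.length_nt for t in self.transcripts]
        total = sum(weights)
        self._fractions = {
            t.transcript_id: w / total for t, w in zip(self.transcripts, weights)
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts]

    def mass_fractions(self) -> dict[str, float]:
        """Per-transcript share of the spiked mass; sums to 1."""
        return dict(self._fractions)

    def with_spike_mass(self, spike_mass_pg: float) -> "ErccMix":
        return ErccMix(self.transcripts, spike_mass_pg)


def mass_fractions(mix: ErccMix) -> dict[str, float]:
    """Functional alias for :meth:`ErccMix.mass_fractions`."""
    return mix.mass_fractions()


def _bundled_path() -> Path:
    return Path(str(resources.files("spikecontam").joinpath("data/ercc_mix.tsv")))


def load_ercc_reference(
    path: str | Path = "bundled",
    spike_mass_pg: float = DEFAULT_SPIKE_MASS_PG,
) -> ErccMix:
    """Load a spike-in reference sheet.

    Parameters
    ----------
    path
        TSV with header columns ``transcript_id``, ``length_nt``,
        ``concentration`` ('#' comment lines permitted), or the literal
        string ``"bundled"`` for the packaged 92-transcript stand-in sheet.
    spike_mass_pg
        Total mass of the mix added per library, picograms.

    Raises
    ------
    ValueError
        On duplicate transcript ids (named in the message) or a
        non-positive length/concentration (reported with its row number).
    """
    p = _bundled_path() if str(path) == "bundled" else Path(path)
    df = pd.read_csv(p, sep="\t", comment="#", dtype={"transcript_id": str})
    required = {"transcript_id", "length_nt", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{p}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{p}: no data rows")

    ids = df["transcript_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{p}: duplicate transcript ids: {', '.join(dupes)}")

    transcripts = []
    for row_number, row in enumerate(df.itertuples(index=False), start=1):
        if row.length_nt <= 0:
            raise ValueError(f"{p} row {row_number}: non-positive length_nt")
        if row.concentration <= 0:
            raise ValueError(f"{p} row {row_number}: non-positive concentration")
        transcripts.append(
            ErccTranscript(
                transcript_id=str(row.transcript_id),
                length_nt=int(row.length_nt),
                concentration=float(row.concentration),
                mix_label=str(getattr(row, "mix_label", "Mix1")),
            )
        )
    return ErccMix(tuple(transcripts), spike_mass_pg=spike_mass_pg)
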