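"""Count-table and metadata IO, and the on-disk result dialects.

Count tables are wide: rows are taxa, columns are samples, the first
column holds taxon IDs and the header row holds sample IDs. Spike-in rows
are recognized by an ID prefix (``ERCC-`` by default), the way taxonomic
classifiers emit spike alignments. All outputs are UTF-8, LF-terminated,
tab-delimited; numbers are printed with six significant digits so reruns
diff byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .model import ContaminantReport

__all__ = [
    "ValidationError",
    "CountTable",
    "SampleMeta",
    "load_counts",
    "load_metadata",
    "write_counts",
    "write_metadata",
    "write_report",
]


class ValidationError(ValueError):
    """An input file violates the table contract."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _sig6(x: float) -> str:
    """Six significant digits; stable across platforms."""
    if isinstance(x, float) and not np.isfinite(x):
        return "inf" if x > 0 else ("-inf" if x < 0 else "nan")
    return f"{x:.6g}"


@dataclass
class CountTable:
    """Integer reads per (taxon, sample), with spike rows marked.

    ``counts`` is a (n_taxa, n_samples) non-negative integer matrix in the
    row/column order of ``taxa``/``samples``.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray
    is_spike: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.is_spike = np.asarray(self.is_spike, dtype=bool)
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError("counts shape does not match taxa/samples")
        if self.is_spike.shape != (len(self.taxa),):
            raise ValidationError("is_spike length does not match taxa")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicated taxon IDs")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicated sample IDs")
        zero = np.asarray(self.counts.sum(axis=0) == 0).nonzero()[0]
        if zero.size:
            names = ", ".join(self.samples[i] for i in zero[:5])
            raise ValidationError(f"sample(s) with zero total reads: {names}")
        self._taxon_index = {t: i for i, t in enumerate(self.taxa)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total_reads(self) -> np.ndarray:
        """Per-sample sums over ALL rows, spike and non-spike alike."""
        return self.counts.sum(axis=0)

    @property
    def ercc_reads(self) -> np.ndarray:
        return self.counts[self.is_spike].sum(axis=0)

    @property
    def nonspike_reads(self) -> np.ndarray:
        return self.counts[~self.is_spike].sum(axis=0)

    def taxon_row(self, taxon_id: str) -> np.ndarray:
        try:
            return self.counts[self._taxon_index[taxon_id]]
        except KeyError:
            raise KeyError(f"taxon {taxon_id!r} not in table") from None

    def sample_pos(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)


@dataclass
class SampleMeta:
    """Per-sample metadata; input mass in picograms when known."""

    sample_id: str
    input_mass_pg: float | None = None
    group: str | None = None
    is_control: bool | None = None

    def __post_init__(self) -> None:
        if self.input_mass_pg is not None and self.input_mass_pg <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: input_mass_pg must be positive"
            )


def load_counts(
    path: str | Path,
    spike_prefix: str = "ERCC-",
    transpose: bool = False,
) -> CountTable:
    """Load a wide taxon-by-sample count table (TSV/CSV by extension).

    Cells must be non-negative integers; violations are reported with
    their (taxon, sample) coordinate. ``transpose=True`` accepts tables
    written samples-by-taxa.
    """
    path = Path(path)
    sep = _sep_for(path)
    # pandas mangles duplicate header names; check the raw header first
    with open(path, encoding="utf-8") as fh:
        header_line = next(
            (ln for ln in fh if ln.strip() and not ln.startswith("#")), ""
        )
    header = [h for h in header_line.rstrip("\n").split(sep)[1:] if h]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        label = "sample" if not transpose else "taxon"
        raise ValidationError(f"{path}: duplicated {label} IDs: {', '.join(dupes)}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: no data rows")
    if transpose:
        df = df.T

    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValidationError(f"{path}: duplicated taxon IDs: {', '.join(dupes)}")
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicated sample IDs: {', '.join(dupes)}")

    values = df.to_numpy()
    numeric = pd.to_numeric(df.stack(), errors="coerce").unstack()
    bad = ~np.isfinite(numeric.to_numpy().astype(float))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{path}: non-numeric count at (taxon {taxa[i]!r}, sample {samples[j]!r}): "
            f"{values[i, j]!r}"
        )
    floats = numeric.to_numpy().astype(float)
    nonint = floats != np.floor(floats)
    if nonint.any():
        i, j = map(int, np.argwhere(nonint)[0])
        raise ValidationError(
            f"{path}: non-integer count at (taxon {taxa[i]!r}, sample {samples[j]!r}): "
            f"{floats[i, j]!r}"
        )
    if (floats < 0).any():
        i, j = map(int, np.argwhere(floats < 0)[0])
        raise ValidationError(
            f"{path}: negative count at (taxon {taxa[i]!r}, sample {samples[j]!r})"
        )
    counts = floats.astype(np.int64)
    is_spike = np.array([t.startswith(spike_prefix) for t in taxa])
    return CountTable(taxa=taxa, samples=samples, counts=counts, is_spike=is_spike)


def write_counts(table: CountTable, path: str | Path) -> None:
    """Write a CountTable in the same wide dialect ``load_counts`` reads."""
    path = Path(path)
    df = table.to_frame()
    df.index.name = "taxon_id"
    df.to_csv(path, sep=_sep_for(path), lineterminator="\n")


def load_metadata(path: str | Path) -> list[SampleMeta]:
    """Load sample metadata (TSV/CSV); only ``sample_id`` is required."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no data rows") from None
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column sample_id")
    ids = [str(s) for s in df["sample_id"]]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample_id: {', '.join(dupes)}")

    metas = []
    for _, row in df.iterrows():
        mass = row.get("input_mass_pg")
        mass = None if mass is None or pd.isna(mass) else float(mass)
        group = row.get("group")
        group = None if group is None or pd.isna(group) else str(group)
        ctrl = row.get("is_control")
        ctrl = None if ctrl is None or pd.isna(ctrl) else bool(ctrl)
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                input_mass_pg=mass,
                group=group,
                is_control=ctrl,
            )
        )
    return metas


def write_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    rows = []
    for m in metas:
        rows.append(
            {
                "sample_id": m.sample_id,
                "input_mass_pg": "" if m.input_mass_pg is None else _sig6(m.input_mass_pg),
                "group": "" if m.group is None else m.group,
                "is_control": "" if m.is_control is None else str(m.is_control).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def _write_tsv(path: Path, header: Iterable[str], rows: Iterable[Iterable[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_report(
    report: "ContaminantReport",
    outdir: str | Path,
    run_info: dict | None = None,
) -> dict[str, Path]:
    """Write the result file set.

    Produces ``taxa_fits.tsv`` (per-taxon regression and classification),
    ``contaminant_mass.tsv`` (attograms per contaminant per sample, with
    mean and SD), ``outliers.tsv`` (studentized residuals and flags),
    ``sample_mass.tsv`` (per-sample mass and its provenance) and
    ``run_info.json``. Sample columns follow the input sample order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fits_by_id = {f.taxon_id: f for f in report.fits}
    rows = []
    for call in report.calls:
        f = fits_by_id.get(call.taxon_id)
        if f is None:
            rows.append(
                [call.taxon_id, "0", "", "", "", "", "",
                 str(call.is_contaminant).lower(), call.reason]
            )
        else:
            rows.append(
                [
                    f.taxon_id,
                    str(f.n_obs),
                    _sig6(f.slope),
                    _sig6(f.intercept),
                    _sig6(f.adj_r2),
                    _sig6(f.p_slope),
                    _sig6(f.p_adj) if f.p_adj is not None else "",
                    str(call.is_contaminant).lower(),
                    call.reason,
                ]
            )
    paths["taxa_fits"] = outdir / "taxa_fits.tsv"
    _write_tsv(
        paths["taxa_fits"],
        ["taxon_id", "n_obs", "slope", "intercept", "adj_r2", "p_slope", "p_adj",
         "is_contaminant", "reason"],
        rows,
    )

    sample_order = [sm.sample_id for sm in report.sample_masses]
    rows = []
    for q in report.masses:
        per = [_sig6(q.per_sample_mass_ag.get(s, 0.0)) for s in sample_order]
        rows.append([q.taxon_id, *per, _sig6(q.mean_mass_ag), _sig6(q.sd_mass_ag)])
    paths["contaminant_mass"] = outdir / "contaminant_mass.tsv"
    _write_tsv(
        paths["contaminant_mass"],
        ["taxon_id", *sample_order, "mean_ag", "sd_ag"],
        rows,
    )

    rows = []
    for oc in report.outliers:
        rows.append(
            [
                oc.sample_id,
                oc.taxon_id,
                _sig6(oc.studentized_residual),
                _sig6(oc.p_value),
                _sig6(oc.p_bonferroni),
                str(oc.is_outlier).lower(),
                str(oc.observed_reads),
                _sig6(oc.expected_reads),
                _sig6(oc.excess_reads),
                _sig6(oc.excess_mass_ag),
                str(oc.taxon_is_contaminant).lower(),
            ]
        )
    paths["outliers"] = outdir / "outliers.tsv"
    _write_tsv(
        paths["outliers"],
        ["sample_id", "taxon_id", "studentized_residual", "p", "p_bonferroni", "flag",
         "observed_reads", "expected_reads", "excess_reads", "excess_mass_ag",
         "taxon_is_contaminant"],
        rows,
    )

    rows = [
        [sm.sample_id, sm.source, _sig6(sm.mass_pg)]
        for sm in report.sample_masses
    ]
    paths["sample_mass"] = outdir / "sample_mass.tsv"
    _write_tsv(paths["sample_mass"], ["sample_id", "mass_source", "mass_pg"], rows)

    info = dict(run_info or {})
    info.setdefault("total_mass_mean_ag", report.total_mass_mean_ag)
    info.setdefault("total_mass_sd_ag", report.total_mass_sd_ag)
    info.setdefault("n_taxa_fitted", len(report.fits))
    info.setdefault("n_contaminants", len(report.masses))
    paths["run_info"] = outdir / "run_info.json"
    with open(paths["run_info"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(info), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
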