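"""Generative count simulator with known injected contamination truth.

The simulator emulates the two experiments the method was built on, as
count tables (no reads, no alignment):

* a **dilution series** — host RNA spanning 1 pg to 2.5 ng in 32
  log-spaced masses, each in triplicate (96 libraries), every library
  spiked with 25 pg of the 92-transcript ERCC mix and carrying a fixed
  attogram-scale panel of reagent contaminants;
* a **serum batch** — 97 libraries with lognormally distributed input
  masses around 100 pg, the same contaminant panel, and one "infected"
  sample carrying excess mass of one contaminant taxon.

Each library is a mass pool: host at the full input mass, optional
community taxa at fixed proportions of the input mass, contaminants at
fixed absolute masses, and the spike split over its transcripts by mass
fraction. Reads are allocated proportional to component mass — the same
assumption the mass-ratio equation makes — via a multinomial draw at the
library's depth (Dirichlet-multinomial when overdispersion > 0). Default
depths are the source experiments' stated medians (26.9M and 34.6M);
simulating counts directly makes full depth essentially free, and at
these depths the printed attogram contaminant masses translate into the
sparse 0-3 read-per-library regime the method actually faces.

All draws come from one seeded generator in a documented order (sample
masses if random, then depths, then per-library counts), so equal seeds
give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ercc import ErccMix, load_ercc_reference
from .io_tables import CountTable, SampleMeta
from .mass import PG_TO_AG

__all__ = [
    "ScenarioConfig",
    "SimulationTruth",
    "default_dilution_config",
    "default_serum_config",
    "dilution_panel",
    "simulate",
]

HOST_TAXON = "Homo_sapiens"

# Named contaminants at their reported mean masses (attograms per library).
NAMED_PANEL: tuple[tuple[str, float], ...] = (
    ("Escherichia_coli", 2.59),
    ("Saccharomyces_cerevisiae", 1.02),
    ("Stenotrophomonas_maltophilia", 0.61),
    ("Cloning_vector", 0.43),
    ("Achromobacter_xylosoxidans", 0.40),
)
MINOR_TAIL_TOTAL_AG = 4.05  # brings the panel total to 9.1 ag
MINOR_TAIL_SIZE = 10
MINOR_TAIL_DECAY = 0.75


def dilution_panel() -> list[tuple[str, float]]:
    """The default contaminant panel: five named taxa plus a geometric
    minor tail of ten unnamed taxa; masses total 9.1 ag per library."""
    a = MINOR_TAIL_TOTAL_AG * (1 - MINOR_TAIL_DECAY) / (1 - MINOR_TAIL_DECAY**MINOR_TAIL_SIZE)
    tail = [
        (f"Minor_contaminant_{i + 1:02d}", a * MINOR_TAIL_DECAY**i)
        for i in range(MINOR_TAIL_SIZE)
    ]
    return list(NAMED_PANEL) + tail


@dataclass
class ScenarioConfig:
    """Everything that defines one simulated experiment.

    ``mass_spacing`` is ``log`` or ``linear`` for a replicated grid of
    ``n_masses`` levels between ``mass_min_pg`` and ``mass_max_pg``
    (inclusive), or ``lognormal`` for ``n_masses`` independent masses
    with median ``mass_median_pg`` and coefficient of variation
    ``mass_cv`` (serum-style batches). ``overdispersion`` scales a
    Dirichlet resampling of the expected read fractions; 0 is a pure
    multinomial.
    """

    name: str = "custom"
    n_masses: int = 32
    replicates: int = 3
    mass_min_pg: float = 1.0
    mass_max_pg: float = 2500.0
    mass_spacing: str = "log"
    mass_median_pg: float = 100.0
    mass_cv: float = 0.5
    spike_mass_pg: float = 25.0
    depth_mean: int = 26_900_000
    depth_cv: float = 0.1
    contaminant_panel: list[tuple[str, float]] = field(default_factory=dilution_panel)
    community_panel: list[tuple[str, float]] = field(default_factory=list)
    host_taxon: str = HOST_TAXON
    infected: tuple[int, str, float] | None = None
    overdispersion: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_masses * self.replicates < 2:
            raise ValueError("need at least 2 libraries")
        if self.mass_spacing not in ("log", "linear", "lognormal"):
            raise ValueError(f"unknown mass_spacing {self.mass_spacing!r}")
        if self.mass_spacing != "lognormal" and not self.mass_min_pg < self.mass_max_pg:
            raise ValueError("mass_min_pg must be below mass_max_pg")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be non-negative")
        props = [p for _, p in self.community_panel]
        if any(not 0 < p < 1 for p in props) or sum(props) > 1:
            raise ValueError("community proportions must be in (0,1) and sum to <= 1")
        if any(m <= 0 for _, m in self.contaminant_panel):
            raise ValueError("contaminant masses must be positive")


@dataclass
class SimulationTruth:
    """Injected ground truth for every simulated library."""

    seed: int
    scenario: str
    host_taxon: str
    contaminant_mass_ag: dict[str, float]
    community_proportions: dict[str, float]
    spike_mass_pg: float
    infected: tuple[int, str, float] | None
    per_sample: dict[str, dict]

    @property
    def infected_sample_id(self) -> str | None:
        if self.infected is None:
            return None
        return list(self.per_sample)[self.infected[0]]


def default_dilution_config(seed: int = 1) -> ScenarioConfig:
    """The HeLa-style dilution series: 32 log-spaced masses from 1 pg to
    2.5 ng in triplicate (96 libraries), 25 pg spike, the 9.1 ag
    contaminant panel, depth ~26.9M reads."""
    return ScenarioConfig(name="dilution", seed=seed)


def default_serum_config(seed: int = 1) -> ScenarioConfig:
    """The serum-style batch: 97 libraries, lognormal masses (median
    100 pg, CV 0.5), the same panel, one sample infected with +50 ag of
    E. coli, depth ~34.6M reads."""
    return ScenarioConfig(
        name="serum",
        n_masses=97,
        replicates=1,
        mass_spacing="lognormal",
        mass_median_pg=100.0,
        mass_cv=0.5,
        depth_mean=34_600_000,
        infected=(42, "Escherichia_coli", 50.0),
        seed=seed,
    )


def _sample_masses(config: ScenarioConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-library masses (pg), sample ids, group labels (draw 1)."""
    if config.mass_spacing == "lognormal":
        sigma = np.sqrt(np.log(1.0 + config.mass_cv**2))
        n = config.n_masses * config.replicates
        masses = rng.lognormal(np.log(config.mass_median_pg), sigma, size=n)
        width = len(str(n))
        ids = [f"{config.name}{k + 1:0{width}d}" for k in range(n)]
        groups = ["" for _ in range(n)]
        return masses, ids, groups
    if config.mass_spacing == "log":
        levels = np.logspace(
            np.log10(config.mass_min_pg), np.log10(config.mass_max_pg), config.n_masses
        )
    else:
        levels = np.linspace(config.mass_min_pg, config.mass_max_pg, config.n_masses)
    masses, ids, groups = [], [], []
    for i, m in enumerate(levels):
        for r in range(config.replicates):
            masses.append(m)
            ids.append(f"m{i + 1:02d}r{r + 1}")
            groups.append(f"mass{i + 1:02d}")
    return np.asarray(masses), ids, groups


def _depths(config: ScenarioConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Library depths, lognormal with the configured mean and CV (draw 2)."""
    if config.depth_cv <= 0:
        return np.full(n, int(config.depth_mean), dtype=np.int64)
    sigma = np.sqrt(np.log(1.0 + config.depth_cv**2))
    mu = np.log(config.depth_mean) - sigma**2 / 2.0
    return np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n))).astype(np.int64)


def simulate(
    config: ScenarioConfig,
    mix: ErccMix | None = None,
) -> tuple[CountTable, list[SampleMeta], SimulationTruth]:
    """Draw one experiment: count table, metadata, and injected truth."""
    if mix is None:
        mix = load_ercc_reference("bundled", spike_mass_pg=config.spike_mass_pg)
    else:
        mix = mix.with_spike_mass(config.spike_mass_pg)

    rng = np.random.default_rng(config.seed)
    masses_pg, sample_ids, groups = _sample_masses(config, rng)
    n = masses_pg.size
    if config.infected is not None and not 0 <= config.infected[0] < n:
        raise ValueError(
            f"infected sample_index {config.infected[0]} out of range 0..{n - 1}"
        )
    depths = _depths(config, n, rng)

    ercc_ids = mix.transcript_ids
    ercc_frac = np.array(list(mix.mass_fractions().values()))
    community = list(config.community_panel)
    contaminants = list(config.contaminant_panel)
    taxa = (
        ercc_ids
        + [config.host_taxon]
        + [t for t, _ in community]
        + [t for t, _ in contaminants]
    )
    n_ercc = len(ercc_ids)
    contam_ids = [t for t, _ in contaminants]

    counts = np.zeros((len(taxa), n), dtype=np.int64)
    per_sample: dict[str, dict] = {}
    spike_ag = config.spike_mass_pg * PG_TO_AG
    for s in range(n):
        m_ag = masses_pg[s] * PG_TO_AG
        comp = np.concatenate(
            [
                ercc_frac * spike_ag,
                [m_ag],
                [p * m_ag for _, p in community],
                [c for _, c in contaminants],
            ]
        )
        injected = {t: float(c) for t, c in contaminants}
        if config.infected is not None and s == config.infected[0]:
            _, inf_taxon, extra = config.infected
            if inf_taxon not in contam_ids:
                raise ValueError(f"infected taxon {inf_taxon!r} not in panel")
            comp[len(taxa) - len(contaminants) + contam_ids.index(inf_taxon)] += extra
            injected[inf_taxon] += extra
        frac = comp / comp.sum()
        if config.overdispersion > 0:
            frac = rng.dirichlet(frac / config.overdispersion)
        counts[:, s] = rng.multinomial(depths[s], frac)

        expected = {config.host_taxon: float(frac[n_ercc])}
        expected.update(
            {t: float(f) for (t, _), f in zip(community, frac[n_ercc + 1 : n_ercc + 1 + len(community)])}
        )
        expected.update(
            {t: float(f) for (t, _), f in zip(contaminants, frac[n_ercc + 1 + len(community) :])}
        )
        expected["spike_total"] = float(frac[:n_ercc].sum())
        per_sample[sample_ids[s]] = {
            "input_mass_pg": float(masses_pg[s]),
            "depth": int(depths[s]),
            "injected_mass_ag": injected,
            "expected_fractions": expected,
        }

    table = CountTable(
        taxa=taxa,
        samples=sample_ids,
        counts=counts,
        is_spike=np.array([t.startswith("ERCC-") for t in taxa]),
    )
    meta = [
        SampleMeta(sample_id=sid, input_mass_pg=float(m), group=g or None)
        for sid, m, g in zip(sample_ids, masses_pg, groups)
    ]
    truth = SimulationTruth(
        seed=config.seed,
        scenario=config.name,
        host_taxon=config.host_taxon,
        contaminant_mass_ag={t: float(c) for t, c in contaminants},
        community_proportions={t: float(p) for t, p in community},
        spike_mass_pg=config.spike_mass_pg,
        infected=config.infected,
        per_sample=per_sample,
    )
    return table, meta, truth
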