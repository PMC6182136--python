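"""Dose-response and genome-size sweeps, and over-production-inhibition calls.

The "rate of transposition" is operationalized as the reciprocal of the
mean first-passage time to the paired-ends complex (synapsis commits the
element), estimated per element from SSA replicates.  Scoring completion
(`DONE`) instead is available via ``target="done"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engines import FirstPassageSample, sample_first_passage, species_predicate
from .model_core import GenomeContext, MutantSpec, RateConstants, concentration_to_count
from .pathways import PathwayKind, build_network

__all__ = [
    "RateEstimate",
    "DoseResponseTable",
    "GenomeSizeTable",
    "OPIVerdict",
    "estimate_transposition_rate",
    "dose_response",
    "genome_size_response",
    "detect_opi",
    "default_dose_grid",
    "default_size_grid",
    "spearman_trend",
]

DEFAULT_Z_CRIT = 3.0
DEFAULT_HORIZON = 2.0e4


@dataclass(frozen=True)
class RateEstimate:
    """Per-element transposition rate with delta-method standard error."""

    rate: float
    se: float
    n_uncensored: int
    censoring_fraction: float

    @property
    def se_defined(self) -> bool:
        return np.isfinite(self.se)


def estimate_transposition_rate(sample: FirstPassageSample) -> RateEstimate:
    """Rate = 1/mean of uncensored first-passage times.

    All-censored samples give rate 0; a single uncensored observation gives
    a rate but an undefined (NaN) standard error.
    """
    n = sample.times.size
    if n == 0:
        return RateEstimate(
            rate=0.0, se=0.0, n_uncensored=0, censoring_fraction=sample.censoring_fraction
        )
    mean = sample.mean
    rate = 1.0 / mean
    if n < 2:
        se = float("nan")
    else:
        # delta method: Var(1/X̄) ≈ Var(X̄) / mean^4
        se = sample.se / (mean * mean)
    return RateEstimate(
        rate=rate, se=se, n_uncensored=n, censoring_fraction=sample.censoring_fraction
    )


def _table_frame(grid_name, grid, estimates, reps) -> pd.DataFrame:
    return pd.DataFrame(
        {
            grid_name: np.asarray(grid, dtype=float),
            "mean_rate": [e.rate for e in estimates],
            "se": [e.se for e in estimates],
            "reps": reps,
            "censored_fraction": [e.censoring_fraction for e in estimates],
        }
    )


@dataclass
class _SweepTable:
    frame: pd.DataFrame
    config: dict

    grid_column = "grid"

    @property
    def grid(self) -> np.ndarray:
        return self.frame[self.grid_column].to_numpy()

    @property
    def rates(self) -> np.ndarray:
        return self.frame["mean_rate"].to_numpy()

    @property
    def ses(self) -> np.ndarray:
        return self.frame["se"].to_numpy()

    def to_tsv(self, path) -> None:
        """Write the table as TSV plus a JSON sidecar with the full config."""
        path = str(path)
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
        with open(path + ".json", "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class DoseResponseTable(_SweepTable):
    grid_column = "concentration_molar"

    def __post_init__(self) -> None:
        grid = self.grid
        if not np.all(np.diff(grid) > 0):
            raise ValueError("concentration grid must be strictly increasing")


@dataclass
class GenomeSizeTable(_SweepTable):
    grid_column = "genome_length_bp"

    def __post_init__(self) -> None:
        grid = self.grid
        if not np.all(np.diff(grid) > 0):
            raise ValueError("genome-size grid must be strictly increasing")


@dataclass(frozen=True)
class OPIVerdict:
    """Outcome of the over-production-inhibition test on a dose response."""

    is_opi: bool
    peak_concentration: float | None
    peak_index: int
    z_vs_first: float
    z_vs_last: float


def default_dose_grid(genome: GenomeContext, n_points: int = 9) -> np.ndarray:
    """Nine log-spaced concentrations spanning 1e-2..1e2 x the end conc."""
    c_end = genome.end_concentration
    return np.geomspace(1e-2 * c_end, 1e2 * c_end, n_points)


def default_size_grid(n_points: int = 7) -> np.ndarray:
    """4 kb plasmid to 4 Gb genome, log-spaced."""
    return np.geomspace(4e3, 4e9, n_points)


def _element_species(network, suffixes) -> list[str]:
    return [
        s
        for s in network.species
        if s.startswith("E") and s.split(":", 1)[1] in suffixes
    ]


def _run_point(
    pathway: PathwayKind,
    rates: RateConstants,
    genome: GenomeContext,
    mutant: MutantSpec,
    conc: float,
    reps: int,
    seed: int,
    horizon: float,
    target: str,
) -> RateEstimate:
    count = concentration_to_count(conc, genome.volume_liters)
    network = build_network(pathway, rates, genome, mutant, count)
    suffixes = ("PEC", "DONE") if target == "pec" else ("DONE",)
    names = _element_species(network, suffixes)
    pred = species_predicate(network, names)
    sample = sample_first_passage(network, pred, reps=reps, seed=seed, horizon=horizon)
    return estimate_transposition_rate(sample)


def dose_response(
    pathway: PathwayKind,
    rates: RateConstants,
    genome: GenomeContext,
    mutant: MutantSpec,
    conc_grid: Sequence[float] | None = None,
    reps: int = 200,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    target: str = "pec",
) -> DoseResponseTable:
    """Sweep transposase concentration and estimate the transposition rate.

    Deterministic given the seed: each grid point receives an independent
    child seed from ``numpy.random.SeedSequence(seed)``.
    """
    if conc_grid is None:
        conc_grid = default_dose_grid(genome)
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0 or np.any(conc_grid < 0) or not np.all(np.diff(conc_grid) > 0):
        raise ValueError("conc_grid must be non-empty, non-negative, strictly increasing")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    point_seeds = _point_seeds(seed, conc_grid.size)
    estimates = [
        _run_point(pathway, rates, genome, mutant, c, reps, s, horizon, target)
        for c, s in zip(conc_grid, point_seeds)
    ]
    config = {
        "kind": "dose_response",
        "pathway": pathway.value,
        "rates": rates.__dict__,
        "genome": genome.__dict__,
        "reps": reps,
        "seed": seed,
        "horizon": horizon,
        "target": target,
    }
    return DoseResponseTable(
        frame=_table_frame("concentration_molar", conc_grid, estimates, reps),
        config=config,
    )


def genome_size_response(
    pathway: PathwayKind,
    rates: RateConstants,
    conc: float,
    size_grid: Sequence[float] | None = None,
    mutant: MutantSpec | None = None,
    reps: int = 200,
    seed: int = 0,
    horizon: float = 1e5,
    target: str = "pec",
    genome_template: GenomeContext | None = None,
) -> GenomeSizeTable:
    """Sweep genome size at fixed transposase concentration.

    With ``k_ns_bind > 0`` the non-specific sites sequester transposase, so
    the effective concentration at the transposon ends falls with genome
    size; with ``cis_acting`` genomes the sweep is flat by construction.
    """
    if not conc > 0:
        raise ValueError("conc must be > 0")
    if size_grid is None:
        size_grid = default_size_grid()
    size_grid = np.asarray(size_grid, dtype=float)
    if not np.all(np.diff(size_grid) > 0):
        raise ValueError("size_grid must be strictly increasing")
    mutant = mutant or MutantSpec.wild_type(
        _default_architecture_for(pathway)
    )
    template = genome_template or GenomeContext(genome_length_bp=int(size_grid[0]))
    point_seeds = _point_seeds(seed, size_grid.size)
    estimates = []
    for size, s in zip(size_grid, point_seeds):
        genome = GenomeContext(
            genome_length_bp=int(size),
            n_elements=template.n_elements,
            volume_liters=template.volume_liters,
            cis_acting=template.cis_acting,
            nonspecific_site_spacing_bp=template.nonspecific_site_spacing_bp,
        )
        estimates.append(
            _run_point(pathway, rates, genome, mutant, conc, reps, s, horizon, target)
        )
    config = {
        "kind": "genome_size_response",
        "pathway": pathway.value,
        "rates": rates.__dict__,
        "concentration_molar": conc,
        "cis_acting": template.cis_acting,
        "reps": reps,
        "seed": seed,
        "horizon": horizon,
        "target": target,
    }
    return GenomeSizeTable(
        frame=_table_frame("genome_length_bp", size_grid, estimates, reps),
        config=config,
    )


def _default_architecture_for(pathway: PathwayKind):
    from .model_core import Architecture

    if pathway is PathwayKind.S_PD:
        return Architecture.MONOMER
    return Architecture.SINGLE_CHAIN_DIMER


def _point_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def detect_opi(table: DoseResponseTable, z_crit: float = DEFAULT_Z_CRIT) -> OPIVerdict:
    """Call over-production inhibition on a dose-response table.

    OPI is present iff some interior grid point's mean rate exceeds both the
    first and the last point's rate by more than ``z_crit`` pooled standard
    errors.
    """
    rates = table.rates
    ses = np.nan_to_num(table.ses, nan=0.0)
    if rates.size < 3 or not np.all(np.isfinite(ses)):
        raise ValueError("need >= 3 grid points with finite SE")
    peak_index = int(np.argmax(rates))
    is_opi = False
    z_first = z_last = -np.inf
    for i in range(1, rates.size - 1):
        zf = _z(rates[i] - rates[0], ses[i], ses[0])
        zl = _z(rates[i] - rates[-1], ses[i], ses[-1])
        if min(zf, zl) > min(z_first, z_last):
            z_first, z_last = zf, zl
        if zf > z_crit and zl > z_crit:
            is_opi = True
            z_first, z_last = zf, zl
            break
    peak_conc = float(table.grid[peak_index]) if is_opi else None
    return OPIVerdict(
        is_opi=is_opi,
        peak_concentration=peak_conc,
        peak_index=peak_index,
        z_vs_first=z_first,
        z_vs_last=z_last,
    )


def _z(diff: float, se_a: float, se_b: float) -> float:
    pooled = float(np.hypot(se_a, se_b))
    if pooled == 0.0:
        return float("inf") if diff > 0 else (-float("inf") if diff < 0 else 0.0)
    return float(diff / pooled)


def spearman_trend(table: _SweepTable, alternative: str = "two-sided"):
    """Spearman rank correlation of mean rate against the swept grid."""
    res = stats.spearmanr(table.grid, table.rates, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
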