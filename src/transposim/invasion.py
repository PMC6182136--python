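"""Generation-based simulation of a transposon invading a genome.

The per-generation transposition probability of each element is derived
from a mean-field first-passage approximation of the assembly kinetics:
the element-level chain (FF -> singly bound -> blocked / PEC) is solved
with a fixed end-binding rate ``b = k_bind * [free transposase]``.

Model internals here are reconstructions, not transcriptions: expression is
linear in copy number under the trans-acting model (``transposase_per_copy
x copies``) and constant under the cis-acting model; the optional
trans-acting inhibitor competitively reduces the synapsis rate by
``1 / (1 + I / Ki)``; each transposition duplicates the element with
``duplication_probability``.  In the S-NEC pathway the capture step is
additionally vulnerable to interruption by free transposase during docking
(factor ``k_dock / (k_dock + b)``), which steepens over-production
inhibition beyond simple end blocking and lets copy-number regulation
emerge without any added component.  All of these choices are echoed in
the output metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import GenomeContext, MutantSpec, RateConstants
from .pathways import PathwayKind, interface_competence_probability

__all__ = [
    "HostParams",
    "InvasionTrajectory",
    "per_generation_rate",
    "mean_field_first_passage_time",
    "run_invasion",
    "summarize_invasion",
]


@dataclass(frozen=True)
class HostParams:
    """Host- and expression-level parameters of the invasion simulation."""

    generations: int = 100
    generation_time: float = 3600.0
    transposase_per_copy: float = 2e-8
    cis_local_concentration: float = 2e-8
    inhibitor_per_copy: float = 0.0
    inhibitor_Ki: float = float("inf")
    duplication_probability: float = 1.0
    copy_cap: int = 10_000
    initial_copies: int = 1
    replicates: int = 100
    seed: int = 0
    docking_interruption: bool = True
    docking_rate: float | None = None
    docking_stages: int = 2

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 <= self.duplication_probability <= 1.0:
            raise ValueError("duplication_probability must lie in [0, 1]")
        if self.copy_cap < self.initial_copies:
            raise ValueError("copy_cap must be >= initial_copies")
        if self.initial_copies < 0:
            raise ValueError("initial_copies must be >= 0")
        if not self.generation_time > 0:
            raise ValueError("generation_time must be > 0")


def mean_field_first_passage_time(
    pathway: PathwayKind,
    b: float,
    k_unbind: float,
    k_synapsis: float,
) -> float:
    """Mean first-passage time to the PEC of the element-level chain.

    ``b`` is the per-end binding rate (s^-1) at fixed free-transposase
    concentration.  States are FF, singly bound (S) and doubly bound (BB);
    in S-NEC capture proceeds from S at ``k_synapsis`` while BB is blocked,
    in S-PD synapsis proceeds from BB at ``k_synapsis``.
    """
    if b <= 0 or k_synapsis <= 0:
        return float("inf")
    if pathway is PathwayKind.S_NEC:
        # closed form: T_FF = 1/(2b) + (1 + b/(2k_-1) + k_-1/(2b)) / k2
        if k_unbind <= 0:
            return 1.0 / (2.0 * b) + 1.0 / k_synapsis if b > 0 else float("inf")
        return (
            1.0 / (2.0 * b)
            + (1.0 + b / (2.0 * k_unbind) + k_unbind / (2.0 * b)) / k_synapsis
        )
    # S-PD (and the double-dimer variant): solve the 3-state linear system
    k1m = k_unbind
    A = np.array(
        [
            [2.0 * b, -2.0 * b, 0.0],
            [-k1m, b + k1m, -b],
            [0.0, -2.0 * k1m, k_synapsis + 2.0 * k1m],
        ]
    )
    try:
        tau = np.linalg.solve(A, np.ones(3))
    except np.linalg.LinAlgError:
        return float("inf")
    t = float(tau[0])
    return t if t > 0 else float("inf")


def per_generation_rate(
    copies: int,
    pathway: PathwayKind,
    rates: RateConstants,
    genome: GenomeContext,
    host: HostParams,
    mutant: MutantSpec | None = None,
) -> float:
    """Per-element transposition probability during one generation.

    Transposase concentration is ``transposase_per_copy * copies`` under
    trans-acting expression, or ``cis_local_concentration`` (independent of
    copy number and genome size) when the genome context is cis-acting.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if copies == 0:
        return 0.0
    if mutant is not None and mutant.interface_dead:
        return 0.0

    if genome.cis_acting:
        conc = host.cis_local_concentration
        free_fraction = 1.0
    else:
        conc = host.transposase_per_copy * copies
        free_fraction = _nonspecific_free_fraction(rates, genome)
    b = rates.k_bind * conc * free_fraction
    if b <= 0:
        return 0.0

    if pathway is PathwayKind.S_NEC:
        k_syn = rates.effective_synapsis
    elif pathway is PathwayKind.DOUBLE_DIMER_SPD and mutant is not None:
        k_syn = rates.k_synapsis * interface_competence_probability(mutant)
    else:
        k_syn = rates.k_synapsis

    inhibitor = host.inhibitor_per_copy * copies
    if inhibitor > 0 and np.isfinite(host.inhibitor_Ki) and host.inhibitor_Ki > 0:
        k_syn = k_syn / (1.0 + inhibitor / host.inhibitor_Ki)

    if pathway is PathwayKind.S_NEC and host.docking_interruption:
        k_dock = host.docking_rate if host.docking_rate is not None else (
            rates.effective_synapsis
        )
        if k_dock > 0:
            # each docking stage can be aborted by a free transposase
            # arriving at the captured naked end before lock-in
            k_syn = k_syn * (k_dock / (k_dock + b)) ** host.docking_stages

    mfpt = mean_field_first_passage_time(pathway, b, rates.k_unbind, k_syn)
    if not np.isfinite(mfpt) or mfpt <= 0:
        return 0.0
    return float(-np.expm1(-host.generation_time / mfpt))


def _nonspecific_free_fraction(rates: RateConstants, genome: GenomeContext) -> float:
    """Equilibrium fraction of transposase not sequestered on the genome."""
    if rates.k_ns_bind <= 0 or rates.k_ns_unbind <= 0:
        return 1.0
    from .model_core import count_to_concentration

    site_conc = count_to_concentration(genome.n_nonspecific_sites, genome.volume_liters)
    return 1.0 / (1.0 + rates.k_ns_bind * site_conc / rates.k_ns_unbind)


@dataclass
class InvasionTrajectory:
    """Per-replicate copy numbers by generation, plus realized events."""

    copies: np.ndarray  # (replicates, generations + 1)
    events: np.ndarray  # (replicates, generations)
    config: dict
    seed: int
    capped: np.ndarray  # (replicates,) bool

    @property
    def generations(self) -> int:
        return self.copies.shape[1] - 1

    @property
    def replicates(self) -> int:
        return self.copies.shape[0]

    def mean_copies(self) -> np.ndarray:
        return self.copies.mean(axis=0)

    def to_tsv(self, path) -> None:
        frame = summarize_invasion(self).frame
        path = str(path)
        frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
        with open(path + ".json", "w") as fh:
            json.dump(self.config, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def run_invasion(
    pathway: PathwayKind,
    rates: RateConstants,
    genome: GenomeContext,
    host: HostParams,
    mutant: MutantSpec | None = None,
) -> InvasionTrajectory:
    """Simulate replicate invasion lineages.

    Each generation every element transposes independently with
    :func:`per_generation_rate`; each transposition adds a copy with
    ``duplication_probability``; copy number is capped (flagged, not an
    error) at ``copy_cap``.
    """
    reps, gens = host.replicates, host.generations
    copies = np.zeros((reps, gens + 1), dtype=np.int64)
    events = np.zeros((reps, gens), dtype=np.int64)
    capped = np.zeros(reps, dtype=bool)
    rate_cache: dict[int, float] = {}

    def p_of(n: int) -> float:
        if n not in rate_cache:
            rate_cache[n] = per_generation_rate(n, pathway, rates, genome, host, mutant)
        return rate_cache[n]

    seeds = np.random.SeedSequence(host.seed).spawn(reps)
    for r, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        n = host.initial_copies
        copies[r, 0] = n
        for g in range(gens):
            p = p_of(n)
            hops = int(rng.binomial(n, p)) if n > 0 and p > 0 else 0
            dup = (
                int(rng.binomial(hops, host.duplication_probability)) if hops else 0
            )
            n = min(n + dup, host.copy_cap)
            if n == host.copy_cap:
                capped[r] = True
            events[r, g] = hops
            copies[r, g + 1] = n
    config = {
        "kind": "invasion",
        "pathway": pathway.value,
        "rates": rates.__dict__,
        "genome": genome.__dict__,
        "host": asdict(host),
        "mutant": None if mutant is None else str(mutant),
    }
    return InvasionTrajectory(
        copies=copies, events=events, config=config, seed=host.seed, capped=capped
    )


@dataclass
class InvasionSummary:
    frame: pd.DataFrame
    plateau: bool
    peak_increment: float
    final_increment: float


def summarize_invasion(
    traj: InvasionTrajectory, plateau_window: float = 0.1, plateau_ratio: float = 0.1
) -> InvasionSummary:
    """Per-generation summary and plateau detection.

    The trajectory plateaus when the mean copy-number increment over the
    final ``plateau_window`` fraction of generations is below
    ``plateau_ratio`` times the peak per-generation increment (a constant
    trajectory trivially plateaus).
    """
    if traj.replicates < 1:
        raise ValueError("need >= 1 replicate")
    mean = traj.copies.mean(axis=0)
    sd = traj.copies.std(axis=0, ddof=1) if traj.replicates > 1 else np.zeros_like(mean)
    q05, q50, q95 = np.quantile(traj.copies, [0.05, 0.5, 0.95], axis=0)
    frame = pd.DataFrame(
        {
            "generation": np.arange(traj.generations + 1),
            "mean_copies": mean,
            "sd": sd,
            "q05": q05,
            "q50": q50,
            "q95": q95,
        }
    )
    increments = np.diff(mean)
    if increments.size == 0:
        return InvasionSummary(frame, True, 0.0, 0.0)
    peak = float(increments.max())
    tail = max(1, int(np.ceil(plateau_window * increments.size)))
    final = float(increments[-tail:].mean())
    plateau = peak <= 0 or final < plateau_ratio * peak
    return InvasionSummary(frame, plateau, peak, final)
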