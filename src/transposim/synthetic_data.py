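"""Archetype parameter sets and synthetic observations.

Only relative magnitudes of the rate constants are anchored by experiment:
the Hsmar1-like archetype has fast specific binding, a long single-end
dwell (mean 600 s, i.e. ``k_unbind = 1/600``), a slow multimer subunit
exchange (``6e-5 s^-1``) and an attenuated synapsis step; the Tn5-like
archetypes have slower binding, a sub-minute dwell and no attenuation.
The absolute magnitudes below are free choices pinned so that an
in-vitro-like reaction (7 nM plasmid substrate, 100 nM transposase, 1 fL
reference volume) completes synapsis well within a four-hour horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    ActiveSite,
    Architecture,
    ArchetypeName,
    GenomeContext,
    InterfaceAllele,
    MutantSpec,
    RateConstants,
)
from .pathways import PathwayKind

__all__ = [
    "ARCHETYPE_DEFAULTS",
    "ArchetypeEnsemble",
    "DwellTimeSample",
    "RateFit",
    "make_archetype_params",
    "make_archetype_ensemble",
    "archetype_pathway",
    "archetype_mutant",
    "sample_dwell_times",
    "fit_dissociation_rate",
    "generate_fixture_run",
    "FIXTURE_SCENARIOS",
]

# Pinned archetype defaults (provenance of the anchored values):
#   HSMAR1 k_unbind      = 1/600 s^-1   <- ~10 min single-end dwell
#   HSMAR1 k_multimer    = 6e-5 s^-1    <- ~3 h subunit-exchange half-life
#   TN5    k_unbind      = 0.1 s^-1     <- sub-minute dwell, single-end
#                                          complex barely detectable
#   HSMAR1 k_bind > TN5 k_bind          <- sequence-specific HTH binding vs
#                                          mostly non-specific contacts
#   HSMAR1 attenuation < 1              <- conformational change after
#                                          single-end binding
# Everything else is calibrated, not measured.
ARCHETYPE_DEFAULTS: dict[ArchetypeName, RateConstants] = {
    ArchetypeName.TN5_MONOMER: RateConstants(
        k_bind=1.0e6,
        k_unbind=0.1,
        k_synapsis=5.0,
        k_post=0.05,
        k_ns_bind=0.06,
        k_ns_unbind=0.002,
        k_multimer_dissoc=0.0,
        synapsis_attenuation=1.0,
    ),
    ArchetypeName.TN5_SCD: RateConstants(
        k_bind=1.0e6,
        k_unbind=0.1,
        k_synapsis=5.0,
        k_post=0.05,
        k_ns_bind=0.06,
        k_ns_unbind=0.002,
        k_multimer_dissoc=0.0,
        synapsis_attenuation=1.0,
    ),
    ArchetypeName.HSMAR1: RateConstants(
        k_bind=1.0e7,
        k_unbind=1.0 / 600.0,
        k_synapsis=5.0,
        k_post=0.05,
        k_ns_bind=0.06,
        k_ns_unbind=0.002,
        k_multimer_dissoc=6.0e-5,
        synapsis_attenuation=0.3,
    ),
}

_ARCHETYPE_PATHWAY = {
    ArchetypeName.TN5_MONOMER: PathwayKind.S_PD,
    ArchetypeName.TN5_SCD: PathwayKind.S_NEC,
    ArchetypeName.HSMAR1: PathwayKind.S_NEC,
}

_ARCHETYPE_ARCHITECTURE = {
    ArchetypeName.TN5_MONOMER: Architecture.MONOMER,
    ArchetypeName.TN5_SCD: Architecture.SINGLE_CHAIN_DIMER,
    ArchetypeName.HSMAR1: Architecture.NATURAL_DIMER,
}


def archetype_pathway(name: ArchetypeName) -> PathwayKind:
    return _ARCHETYPE_PATHWAY[ArchetypeName(name)]


def archetype_mutant(name: ArchetypeName) -> MutantSpec:
    return MutantSpec.wild_type(_ARCHETYPE_ARCHITECTURE[ArchetypeName(name)])


@dataclass(frozen=True)
class ArchetypeEnsemble:
    """Jittered parameter draws around one archetype's defaults."""

    name: ArchetypeName
    members: tuple[RateConstants, ...]
    seed: int
    jitter: float


@dataclass(frozen=True)
class DwellTimeSample:
    """Exponentially distributed dwell-time observations."""

    times: np.ndarray
    true_rate: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.times <= 0):
            raise ValueError("dwell times must be positive")


@dataclass(frozen=True)
class RateFit:
    """Maximum-likelihood dissociation-rate estimate with an exact CI."""

    rate: float
    ci_low: float
    ci_high: float
    n: int
    n_censored: int = 0


def make_archetype_params(
    name: ArchetypeName | str, seed: int = 0, jitter: float = 1.0
) -> RateConstants:
    """One parameter draw for an archetype.

    ``jitter == 1`` returns the pinned defaults exactly.  Larger values
    apply multiplicative log-normal jitter (sigma = ln(jitter)) to every
    rate constant, with rejection so that the qualitative orderings against
    the Tn5 defaults always hold.
    """
    name = ArchetypeName(name)
    if jitter < 1.0:
        raise ValueError("jitter must be >= 1")
    base = ARCHETYPE_DEFAULTS[name]
    if jitter == 1.0:
        return base
    rng = np.random.Generator(np.random.PCG64(seed))
    return _jitter_draw(name, base, rng, jitter)


def make_archetype_ensemble(
    name: ArchetypeName | str, n: int, seed: int = 0, jitter: float = 1.5
) -> ArchetypeEnsemble:
    """An ensemble of ``n`` jittered draws for one archetype."""
    name = ArchetypeName(name)
    base = ARCHETYPE_DEFAULTS[name]
    rng = np.random.Generator(np.random.PCG64(seed))
    members = tuple(_jitter_draw(name, base, rng, jitter) for _ in range(n))
    return ArchetypeEnsemble(name=name, members=members, seed=seed, jitter=jitter)


def _jitter_draw(
    name: ArchetypeName,
    base: RateConstants,
    rng: np.random.Generator,
    jitter: float,
) -> RateConstants:
    tn5 = ARCHETYPE_DEFAULTS[ArchetypeName.TN5_SCD]
    sigma = np.log(jitter)
    for _ in range(1000):
        factor = lambda: float(np.exp(rng.normal(0.0, sigma)))  # noqa: E731
        draw = replace(
            base,
            k_bind=base.k_bind * factor(),
            k_unbind=base.k_unbind * factor(),
            k_synapsis=base.k_synapsis * factor(),
            k_post=base.k_post * factor(),
            k_ns_bind=base.k_ns_bind * factor(),
            k_ns_unbind=base.k_ns_unbind * factor(),
            k_multimer_dissoc=base.k_multimer_dissoc * factor(),
            synapsis_attenuation=(
                min(base.synapsis_attenuation * factor(), 0.999)
                if name is ArchetypeName.HSMAR1
                else 1.0
            ),
        )
        if name is ArchetypeName.HSMAR1:
            ok = (
                draw.k_bind > tn5.k_bind
                and draw.k_unbind < tn5.k_unbind
                and draw.synapsis_attenuation < 1.0
            )
        else:
            ok = draw.synapsis_attenuation == 1.0
        if ok:
            return draw
    raise RuntimeError("jitter rejection failed to converge")


def sample_dwell_times(true_rate: float, n: int, seed: int = 0) -> DwellTimeSample:
    """``n`` i.i.d. exponential dwell times with the given rate."""
    if not true_rate > 0:
        raise ValueError("true_rate must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    times = rng.exponential(1.0 / true_rate, size=n)
    times = np.maximum(times, np.finfo(float).tiny)
    return DwellTimeSample(times=times, true_rate=true_rate, seed=seed)


def fit_dissociation_rate(
    sample: DwellTimeSample | np.ndarray,
    confidence: float = 0.95,
    n_censored: int = 0,
    censor_time: float | None = None,
) -> RateFit:
    """MLE of an exponential dissociation rate with an exact gamma CI.

    For fully observed data the MLE is ``1/mean`` and ``2 n k / k_hat`` is
    chi-square with ``2n`` degrees of freedom, giving the exact interval.
    With ``n_censored`` observations truncated at ``censor_time`` the MLE
    becomes ``n_events / (sum(times) + n_censored * censor_time)`` and the
    interval uses ``2 n_events`` degrees of freedom.
    """
    times = sample.times if isinstance(sample, DwellTimeSample) else np.asarray(sample)
    n = times.size
    if n < 2:
        raise ValueError("need at least two observations")
    total = float(times.sum())
    if total <= 0:
        raise ValueError("degenerate sample: total observation time is zero")
    if n_censored:
        if censor_time is None:
            raise ValueError("censor_time required when n_censored > 0")
        total += n_censored * censor_time
    alpha = 1.0 - confidence
    rate = n / total
    dof = 2 * n
    ci_low = stats.chi2.ppf(alpha / 2.0, dof) / (2.0 * total)
    ci_high = stats.chi2.ppf(1.0 - alpha / 2.0, dof) / (2.0 * total)
    return RateFit(rate=rate, ci_low=ci_low, ci_high=ci_high, n=n, n_censored=n_censored)


FIXTURE_SCENARIOS = (
    "snec_basic",
    "spd_basic",
    "g462d_dead",
    "ade_single_end",
    "hsmar1_opi",
    "tn5_no_opi",
    "invasion_plateau",
)


def generate_fixture_run(scenario: str, seed: int, outdir) -> list[Path]:
    """Write a config + golden-output fixture bundle for one scenario.

    Regeneration with the same seed is byte-identical.  Returns the list of
    files written.
    """
    from . import engines, invasion, sweeps
    from .pathways import build_network, predict_cleavage_products

    if scenario not in FIXTURE_SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {FIXTURE_SCENARIOS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
        written.append(path)

    def write_tsv(name: str, frame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
        written.append(path)

    genome = GenomeContext(genome_length_bp=4000)
    write_json(
        f"{scenario}.config.json",
        {"scenario": scenario, "seed": seed, "package": "transposim"},
    )

    if scenario in ("snec_basic", "spd_basic"):
        name = ArchetypeName.TN5_SCD if scenario == "snec_basic" else ArchetypeName.TN5_MONOMER
        rates = make_archetype_params(name)
        net = build_network(
            archetype_pathway(name), rates, genome, archetype_mutant(name), 20
        )
        traj = engines.simulate_ssa(net, horizon=200.0, seed=seed, max_events=20_000)
        frame = pd.DataFrame(traj.states, columns=traj.species)
        frame.insert(0, "time", traj.times)
        write_tsv(f"{scenario}.trajectory.tsv", frame)
    elif scenario == "g462d_dead":
        rates = make_archetype_params(ArchetypeName.TN5_SCD)
        mutant = MutantSpec(
            architecture=Architecture.SINGLE_CHAIN_DIMER,
            subunit_a_interface=InterfaceAllele.G462D,
        )
        net = build_network(PathwayKind.S_NEC, rates, genome, mutant, 20)
        pred = engines.species_predicate(net, ["E0:PEC", "E0:DONE"])
        fp = engines.sample_first_passage(net, pred, reps=100, seed=seed, horizon=200.0)
        write_json(
            "g462d_dead.result.json",
            {
                "pec_events": int(fp.times.size),
                "censored": fp.n_censored,
                "reps": fp.reps,
            },
        )
    elif scenario == "ade_single_end":
        mutant = MutantSpec(
            architecture=Architecture.SINGLE_CHAIN_DIMER,
            subunit_a_active_site=ActiveSite.ADE,
        )
        pred = predict_cleavage_products(mutant, PathwayKind.S_NEC)
        write_json(
            "ade_single_end.result.json",
            {"products": pred.products, "relative_activity": pred.relative_activity},
        )
    elif scenario in ("hsmar1_opi", "tn5_no_opi"):
        name = ArchetypeName.HSMAR1 if scenario == "hsmar1_opi" else ArchetypeName.TN5_SCD
        rates = make_archetype_params(name)
        table = sweeps.dose_response(
            archetype_pathway(name),
            rates,
            genome,
            archetype_mutant(name),
            reps=100,
            seed=seed,
        )
        verdict = sweeps.detect_opi(table)
        write_tsv(f"{scenario}.dose_response.tsv", table.frame)
        write_json(
            f"{scenario}.verdict.json",
            {"is_opi": verdict.is_opi, "peak_index": verdict.peak_index},
        )
    elif scenario == "invasion_plateau":
        rates = make_archetype_params(ArchetypeName.HSMAR1)
        host = invasion.HostParams(
            generations=80, replicates=30, seed=seed, transposase_per_copy=2e-8
        )
        traj = invasion.run_invasion(
            PathwayKind.S_NEC, rates, genome, host, archetype_mutant(ArchetypeName.HSMAR1)
        )
        summary = invasion.summarize_invasion(traj)
        write_tsv("invasion_plateau.summary.tsv", summary.frame)
        write_json("invasion_plateau.result.json", {"plateau": bool(summary.plateau)})
    return written
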