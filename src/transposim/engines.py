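"""Simulation engines for reaction networks.

Three complementary routes:

* :func:`simulate_ssa` — exact stochastic simulation (Gillespie direct
  method) with explicit integer seeding and bit-reproducible event logs.
* :func:`integrate_mean_field` — deterministic mass-action ODE system over
  species means (scipy ``solve_ivp``).
* :func:`solve_ctmc_exact` — brute-force transient solution of the
  continuous-time Markov chain on an enumerated state space; the oracle the
  stochastic engine is validated against.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .pathways import ReactionNetwork

__all__ = [
    "SystemState",
    "Trajectory",
    "DistributionSnapshot",
    "FirstPassageSample",
    "simulate_ssa",
    "integrate_mean_field",
    "solve_ctmc_exact",
    "sample_first_passage",
    "species_predicate",
    "StateSpaceCapExceeded",
]

STATE_SPACE_CAP = 20_000


class StateSpaceCapExceeded(RuntimeError):
    """Raised when CTMC enumeration exceeds the hard state cap."""


@dataclass
class SystemState:
    counts: np.ndarray
    time: float


@dataclass
class Trajectory:
    """Time-stamped species counts from SSA or the mean-field integrator."""

    species: list[str]
    times: np.ndarray
    states: np.ndarray  # shape (n_snapshots, n_species)
    labels: list[str]
    seed: int | None
    terminal: str  # "horizon" | "exhausted" | "event_cap"

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def count_series(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]


@dataclass
class DistributionSnapshot:
    """Exact state distribution of a small network at one horizon."""

    species: list[str]
    states: list[tuple[int, ...]]
    probabilities: np.ndarray
    horizon: float
    mfpt_to_target: float | None = None

    def probability_of(self, predicate: Callable[[np.ndarray], bool]) -> float:
        mass = 0.0
        for state, p in zip(self.states, self.probabilities):
            if predicate(np.asarray(state)):
                mass += p
        return float(mass)

    def marginal(self, species: str) -> dict[int, float]:
        idx = self.species.index(species)
        out: dict[int, float] = {}
        for state, p in zip(self.states, self.probabilities):
            out[state[idx]] = out.get(state[idx], 0.0) + float(p)
        return out


@dataclass
class FirstPassageSample:
    """First-passage times over SSA replicates, with censoring bookkeeping."""

    times: np.ndarray  # uncensored first-passage times only
    n_censored: int
    reps: int
    horizon: float
    seed: int

    @property
    def censoring_fraction(self) -> float:
        return self.n_censored / self.reps

    @property
    def mean(self) -> float:
        return float(np.mean(self.times)) if self.times.size else float("nan")

    @property
    def median(self) -> float:
        return float(np.median(self.times)) if self.times.size else float("nan")

    @property
    def se(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return float(np.std(self.times, ddof=1) / np.sqrt(self.times.size))


def _reaction_arrays(network: ReactionNetwork):
    """Precompute flat arrays describing the reaction channels."""
    idx = {name: i for i, name in enumerate(network.species)}
    n_rxn = len(network.reactions)
    r1 = np.full(n_rxn, -1, dtype=np.int64)
    r2 = np.full(n_rxn, -1, dtype=np.int64)
    rates = np.empty(n_rxn)
    deltas = np.zeros((n_rxn, len(network.species)), dtype=np.int64)
    for j, rxn in enumerate(network.reactions):
        rates[j] = rxn.rate
        flat: list[int] = []
        for name, stoich in rxn.reactants:
            flat.extend([idx[name]] * stoich)
            deltas[j, idx[name]] -= stoich
        for name, stoich in rxn.products:
            deltas[j, idx[name]] += stoich
        if len(flat) > 2:
            raise ValueError("at most bimolecular channels are supported")
        if len(flat) >= 1:
            r1[j] = flat[0]
        if len(flat) == 2:
            r2[j] = flat[1]
    return r1, r2, rates, deltas


def _propensities(x: np.ndarray, r1, r2, rates) -> np.ndarray:
    a = rates.copy()
    mask1 = r1 >= 0
    a[mask1] *= x[r1[mask1]]
    mask2 = r2 >= 0
    same = mask2 & (r1 == r2)
    diff = mask2 & ~same
    a[diff] *= x[r2[diff]]
    # A + A channels use n(n-1)/2 combinatorics
    a[same] *= np.maximum(x[r2[same]] - 1, 0) / 2.0
    return a


def simulate_ssa(
    network: ReactionNetwork,
    horizon: float,
    seed: int,
    max_events: int = 1_000_000,
    record: bool = True,
) -> Trajectory:
    """Exact stochastic simulation by the direct method.

    Identical ``(network, horizon, seed)`` inputs yield bit-identical event
    logs.  Exhaustion of all propensities before the horizon terminates the
    run cleanly (``terminal == "exhausted"``) rather than raising.
    """
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    r1, r2, rates, deltas = _reaction_arrays(network)
    labels = [rxn.label for rxn in network.reactions]

    x = np.array(network.initial_counts, dtype=np.int64)
    t = 0.0
    times = [0.0]
    states = [x.copy()]
    events: list[str] = []
    terminal = "horizon"
    for _ in range(max_events):
        a = _propensities(x, r1, r2, rates)
        a0 = a.sum()
        if a0 <= 0.0:
            terminal = "exhausted"
            break
        t_next = t + rng.exponential(1.0 / a0)
        u = rng.random() * a0
        if t_next > horizon:
            break
        j = int(np.searchsorted(np.cumsum(a), u, side="right"))
        j = min(j, len(a) - 1)
        x = x + deltas[j]
        t = t_next
        if record:
            times.append(t)
            states.append(x.copy())
            events.append(labels[j])
    else:
        terminal = "event_cap"
    if terminal in ("horizon", "exhausted"):
        end = horizon if terminal == "horizon" else min(horizon, t)
    else:
        end = t
    if not record or times[-1] < end:
        times.append(end)
        states.append(x.copy())
        events.append("<end>")
    return Trajectory(
        species=list(network.species),
        times=np.asarray(times),
        states=np.asarray(states),
        labels=events,
        seed=seed,
        terminal=terminal,
    )


def integrate_mean_field(
    network: ReactionNetwork,
    horizon: float,
    grid: Sequence[float] | None = None,
    tol: float = 1e-8,
) -> Trajectory:
    """Mass-action mean-field ODE solution of the network.

    Uses the same stochastic rate constants as the SSA, so the state
    variables are expected molecule counts.
    """
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    if not tol > 0:
        raise ValueError("tol must be > 0")
    r1, r2, rates, deltas = _reaction_arrays(network)
    deltas_f = deltas.astype(float)
    x0 = np.array(network.initial_counts, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, horizon, 101)
    grid = np.asarray(grid, dtype=float)

    def rhs(_t, x):
        xa = np.maximum(x, 0.0)
        a = _propensities(xa, r1, r2, rates)
        return a @ deltas_f

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        x0,
        t_eval=grid,
        method="LSODA",
        rtol=tol,
        atol=tol * max(1.0, x0.max(initial=1.0)),
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return Trajectory(
        species=list(network.species),
        times=sol.t,
        states=sol.y.T,
        labels=[],
        seed=None,
        terminal="horizon",
    )


def _enumerate_states(network: ReactionNetwork, cap: int = STATE_SPACE_CAP):
    """Breadth-first reachable-state enumeration with a hard cap."""
    r1, r2, rates, deltas = _reaction_arrays(network)
    x0 = tuple(int(c) for c in network.initial_counts)
    index = {x0: 0}
    order = [x0]
    edges: list[tuple[int, int, float]] = []
    queue = deque([x0])
    while queue:
        state = queue.popleft()
        i = index[state]
        x = np.asarray(state, dtype=np.int64)
        a = _propensities(x, r1, r2, rates)
        for j, aj in enumerate(a):
            if aj <= 0:
                continue
            nxt = tuple((x + deltas[j]).tolist())
            if nxt not in index:
                if len(index) >= cap:
                    raise StateSpaceCapExceeded(
                        f"reachable state space exceeds {cap} states; use simulate_ssa"
                    )
                index[nxt] = len(order)
                order.append(nxt)
                queue.append(nxt)
            edges.append((i, index[nxt], float(aj)))
    return order, index, edges


def solve_ctmc_exact(
    network: ReactionNetwork,
    horizon: float,
    target: Callable[[np.ndarray], bool] | None = None,
    cap: int = STATE_SPACE_CAP,
) -> DistributionSnapshot:
    """Exact transient distribution at ``horizon`` via the matrix exponential.

    When ``target`` is given and reachable with probability one, the mean
    first-passage time from the initial state to the target set is solved
    from the generator restricted to non-target states and attached to the
    snapshot (``mfpt_to_target``; ``inf`` if the target can be missed,
    ``None`` if unreachable).
    """
    if not horizon > 0:
        raise ValueError("horizon must be > 0")
    order, _index, edges = _enumerate_states(network, cap=cap)
    n = len(order)
    rows = [e[0] for e in edges]
    cols = [e[1] for e in edges]
    vals = [e[2] for e in edges]
    diag = np.zeros(n)
    for i, _, v in edges:
        diag[i] -= v
    Q = sp.csr_matrix(
        (vals + diag.tolist(), (rows + list(range(n)), cols + list(range(n)))),
        shape=(n, n),
    )
    p0 = np.zeros(n)
    p0[0] = 1.0
    p = spla.expm_multiply(Q.T * horizon, p0)
    p = np.clip(p, 0.0, None)
    p /= p.sum()

    mfpt: float | None = None
    if target is not None:
        target_mask = np.array([bool(target(np.asarray(s))) for s in order])
        if target_mask.any():
            mfpt = _mfpt_from_initial(Q, target_mask)
        else:
            mfpt = None
    return DistributionSnapshot(
        species=list(network.species),
        states=order,
        probabilities=p,
        horizon=horizon,
        mfpt_to_target=mfpt,
    )


def _mfpt_from_initial(Q: sp.csr_matrix, target_mask: np.ndarray) -> float:
    if target_mask[0]:
        return 0.0
    trans = ~target_mask
    Qtt = Q[trans][:, trans].tocsc()
    # states that cannot reach the target absorb elsewhere -> infinite MFPT
    ones = np.ones(Qtt.shape[0])
    try:
        tau = spla.spsolve(-Qtt, ones)
    except RuntimeError:
        return float("inf")
    if np.any(~np.isfinite(tau)) or np.any(tau < 0):
        return float("inf")
    # exit-rate deficit means some transient state is itself absorbing
    init_pos = int(np.cumsum(trans)[0]) - 1
    out_rates = -Qtt.diagonal()
    reach = np.asarray(Q[trans][:, target_mask].sum(axis=1)).ravel()
    if np.any((out_rates <= 0) & (reach <= 0)):
        # a transient absorbing state exists; MFPT finite only if unreachable
        return float("inf")
    return float(tau[init_pos])


def species_predicate(
    network: ReactionNetwork, names: Sequence[str], minimum: int = 1
) -> Callable[[np.ndarray], bool]:
    """Predicate: total count over ``names`` is at least ``minimum``."""
    idxs = [network.species_index(n) for n in names]

    def pred(x: np.ndarray) -> bool:
        return int(sum(x[i] for i in idxs)) >= minimum

    return pred


def sample_first_passage(
    network: ReactionNetwork,
    target: Callable[[np.ndarray], bool],
    reps: int,
    seed: int,
    horizon: float = 1e5,
    max_events: int = 5_000_000,
) -> FirstPassageSample:
    """Sample the first time the target predicate holds, over replicates.

    Replicates that never satisfy the predicate before the horizon are
    recorded as censored, not raised.  A network where the target is
    unreachable therefore yields a 100% censoring fraction.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    r1, r2, rates, deltas = _reaction_arrays(network)
    x0 = np.array(network.initial_counts, dtype=np.int64)
    if target(x0):
        return FirstPassageSample(
            times=np.zeros(reps), n_censored=0, reps=reps, horizon=horizon, seed=seed
        )
    seeds = np.random.SeedSequence(seed).spawn(reps)
    times: list[float] = []
    n_censored = 0
    for ss in seeds:
        rng = np.random.Generator(np.random.PCG64(ss))
        x = x0.copy()
        t = 0.0
        hit = False
        for _ in range(max_events):
            a = _propensities(x, r1, r2, rates)
            a0 = a.sum()
            if a0 <= 0.0:
                break
            t += rng.exponential(1.0 / a0)
            if t > horizon:
                break
            u = rng.random() * a0
            j = int(np.searchsorted(np.cumsum(a), u, side="right"))
            j = min(j, len(a) - 1)
            x += deltas[j]
            if target(x):
                hit = True
                break
        if hit:
            times.append(t)
        else:
            n_censored += 1
    return FirstPassageSample(
        times=np.asarray(times),
        n_censored=n_censored,
        reps=reps,
        horizon=horizon,
        seed=seed,
    )
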