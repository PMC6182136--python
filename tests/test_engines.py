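import numpy as np
import pytest

from transposim.engines import (
    StateSpaceCapExceeded,
    integrate_mean_field,
    sample_first_passage,
    simulate_ssa,
    solve_ctmc_exact,
    species_predicate,
)
from transposim.model_core import (
    AVOGADRO,
    Architecture,
    GenomeContext,
    InterfaceAllele,
    MutantSpec,
    RateConstants,
)
from transposim.pathways import PathwayKind, build_network


def _pec_predicate(net):
    return species_predicate(net, ["E0:PEC", "E0:DONE"])


class TestSimulateSSA:
    def test_zero_transposase_constant(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 0)
        traj = simulate_ssa(net, horizon=100.0, seed=1)
        assert traj.terminal == "exhausted"
        assert np.array_equal(traj.states[0], traj.states[-1])
        assert traj.labels in ([], ["<end>"])

    def test_seed_replay_bit_identical(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 4)
        a = simulate_ssa(net, horizon=50.0, seed=7)
        b = simulate_ssa(net, horizon=50.0, seed=7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        assert a.labels == b.labels

    def test_different_seeds_differ(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 4)
        a = simulate_ssa(net, horizon=50.0, seed=7)
        b = simulate_ssa(net, horizon=50.0, seed=8)
        assert not (np.array_equal(a.times, b.times) and a.labels == b.labels)

    def test_conservation_at_every_event(self, hsmar1_rates, plasmid_genome):
        wt = MutantSpec.wild_type(Architecture.NATURAL_DIMER)
        net = build_network(PathwayKind.S_NEC, hsmar1_rates, plasmid_genome, wt, 6)
        traj = simulate_ssa(net, horizon=500.0, seed=3)
        weights = np.array([net.subunit_weights.get(s, 0) for s in net.species])
        totals = traj.states @ weights
        assert np.all(totals == totals[0])
        elements = traj.states[:, [i for i, s in enumerate(net.species) if s.startswith("E")]]
        assert np.all(elements.sum(axis=1) == 1)

    def test_counts_never_negative(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 4)
        traj = simulate_ssa(net, horizon=200.0, seed=11)
        assert traj.states.min() >= 0

    def test_times_strictly_increasing(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 4)
        traj = simulate_ssa(net, horizon=50.0, seed=5)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[0] == 0.0


class TestMeanField:
    def test_zero_transposase_constant(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 0)
        traj = integrate_mean_field(net, horizon=100.0)
        assert np.allclose(traj.states, traj.states[0], atol=1e-9)

    def test_linear_relaxation_matches_closed_form(self, plasmid_genome):
        # bind/unbind only: d[BF+FB]/dt = 2 b (1-x) - k_off x with one dimer;
        # for a single element and constant P=n the occupied fraction relaxes
        # exponentially; with k_synapsis -> 0 propensity structure is linear
        rates = RateConstants(k_bind=1e7, k_unbind=0.02, k_synapsis=0.0, k_post=0.0)
        net = build_network(
            PathwayKind.S_NEC,
            rates,
            plasmid_genome,
            MutantSpec.wild_type(Architecture.SINGLE_CHAIN_DIMER),
            1,
        )
        horizon, grid = 400.0, np.linspace(0, 400.0, 21)
        traj = integrate_mean_field(net, horizon, grid=grid, tol=1e-10)
        b = rates.k_bind / (AVOGADRO * plasmid_genome.volume_liters)
        # mean-field ODE for occupancy y = [BF]+[FB]+2[BB] is nonlinear in
        # general; with a single protein [BB]=0 and y' = 2b(1-y)^2 ... use the
        # exact linear sub-case instead: P treated large via k_unbind only.
        # Here we check the simplest analytic invariant: total elements = 1
        # and the free-protein + bound-protein balance at every grid point.
        p = traj.count_series("P")
        occupied = (
            traj.count_series("E0:BF")
            + traj.count_series("E0:FB")
            + 2 * traj.count_series("E0:BB")
        )
        assert np.allclose(p + occupied, 1.0, atol=1e-7)
        # and against an independent numeric reference (tiny dt Euler)
        y = np.zeros(3)  # FF->1-..., actually integrate [BF+FB, BB, P] crude
        ff, bf, bb, pfree = 1.0, 0.0, 0.0, 1.0
        dt = 0.001
        ts = [0.0]
        ref = []
        t = 0.0
        for k in range(int(horizon / dt)):
            dbind1 = 2 * b * pfree * ff
            dbind2 = b * pfree * bf
            dunb1 = rates.k_unbind * bf
            dunb2 = 2 * rates.k_unbind * bb
            ff += dt * (-dbind1 + dunb1)
            bf += dt * (dbind1 - dbind2 - dunb1 + dunb2)
            bb += dt * (dbind2 - dunb2)
            pfree += dt * (-dbind1 - dbind2 + dunb1 + dunb2)
            t += dt
        singly = traj.count_series("E0:BF")[-1] + traj.count_series("E0:FB")[-1]
        assert singly == pytest.approx(bf, abs=5e-3)

    def test_conserved_totals_along_solution(self, tn5_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, tn5_rates, plasmid_genome, scd_wt, 20)
        traj = integrate_mean_field(net, horizon=100.0, tol=1e-9)
        weights = np.array([net.subunit_weights.get(s, 0) for s in net.species])
        totals = traj.states @ weights
        assert np.allclose(totals, totals[0], rtol=1e-7)

    def test_snec_accumulates_faster_than_spd(self, plasmid_genome):
        # fast-synapsis / fast-unbinding regime: naked-end capture beats
        # protein dimerization at every time point
        rates = RateConstants(k_bind=1e6, k_unbind=0.1, k_synapsis=5.0, k_post=0.1)
        grid = np.linspace(0.0, 300.0, 16)
        done = {}
        for pathway, arch in (
            (PathwayKind.S_NEC, Architecture.SINGLE_CHAIN_DIMER),
            (PathwayKind.S_PD, Architecture.MONOMER),
        ):
            net = build_network(
                pathway, rates, plasmid_genome, MutantSpec.wild_type(arch), 10
            )
            traj = integrate_mean_field(net, 300.0, grid=grid)
            done[pathway] = traj.count_series("E0:PEC") + traj.count_series("E0:DONE")
        assert np.all(done[PathwayKind.S_NEC][1:] >= done[PathwayKind.S_PD][1:])


class TestCTMCOracle:
    def test_distribution_normalized(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 3)
        snap = solve_ctmc_exact(net, horizon=25.0)
        assert snap.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(snap.probabilities >= 0)

    def test_absorbing_done_monotone(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 2)
        idx_done = None
        masses = []
        for horizon in (10.0, 100.0, 1000.0, 10000.0):
            snap = solve_ctmc_exact(net, horizon=horizon)
            i = snap.species.index("E0:DONE")
            masses.append(sum(p for s, p in zip(snap.states, snap.probabilities) if s[i] == 1))
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))
        assert masses[-1] > 0.999

    def test_two_stage_series_closed_form(self, plasmid_genome, scd_wt):
        # k_unbind = 0, no ns: first passage to PEC is binding (rate 2*b)
        # then capture (rate k2): MFPT = 1/(2b) + 1/k2
        rates = RateConstants(k_bind=2e7, k_unbind=0.0, k_synapsis=0.04, k_post=0.0)
        net = build_network(PathwayKind.S_NEC, rates, plasmid_genome, scd_wt, 1)
        b = rates.k_bind / (AVOGADRO * plasmid_genome.volume_liters)
        expected = 1.0 / (2.0 * b) + 1.0 / rates.k_synapsis
        snap = solve_ctmc_exact(net, horizon=10.0, target=_pec_predicate(net))
        assert snap.mfpt_to_target == pytest.approx(expected, rel=1e-9)

    def test_ssa_mfpt_matches_oracle(self, plasmid_genome, scd_wt):
        rates = RateConstants(k_bind=2e7, k_unbind=0.0, k_synapsis=0.04, k_post=0.0)
        net = build_network(PathwayKind.S_NEC, rates, plasmid_genome, scd_wt, 1)
        snap = solve_ctmc_exact(net, horizon=10.0, target=_pec_predicate(net))
        fp = sample_first_passage(net, _pec_predicate(net), reps=2000, seed=42, horizon=1e4)
        assert fp.censoring_fraction == 0.0
        assert abs(fp.mean - snap.mfpt_to_target) < 3 * fp.se

    def test_cap_exceeded(self, tn5_rates, scd_wt):
        genome = GenomeContext(genome_length_bp=10_000_000)
        net = build_network(PathwayKind.S_NEC, tn5_rates, genome, scd_wt, 50)
        with pytest.raises(StateSpaceCapExceeded):
            solve_ctmc_exact(net, horizon=10.0, cap=50)

    def test_unreachable_target_is_none(self, tn5_rates, plasmid_genome):
        mutant = MutantSpec(
            architecture=Architecture.SINGLE_CHAIN_DIMER,
            subunit_a_interface=InterfaceAllele.G462D,
        )
        net = build_network(PathwayKind.S_NEC, tn5_rates, plasmid_genome, mutant, 2)
        snap = solve_ctmc_exact(net, horizon=10.0, target=_pec_predicate(net))
        assert snap.mfpt_to_target is None


class TestSSAvsOracleDistribution:
    @pytest.mark.parametrize("case", range(3))
    def test_chi_square_agreement(self, case, plasmid_genome):
        rng = np.random.Generator(np.random.PCG64(100 + case))
        rates = RateConstants(
            k_bind=10 ** rng.uniform(6.5, 7.5),
            k_unbind=10 ** rng.uniform(-2, -1),
            k_synapsis=10 ** rng.uniform(-2, -0.5),
            k_post=10 ** rng.uniform(-3, -2),
        )
        pathway = PathwayKind.S_NEC if case % 2 == 0 else PathwayKind.S_PD
        arch = (
            Architecture.SINGLE_CHAIN_DIMER
            if pathway is PathwayKind.S_NEC
            else Architecture.MONOMER
        )
        net = build_network(
            pathway, rates, plasmid_genome, MutantSpec.wild_type(arch), 2 + case
        )
        horizon = 40.0
        snap = solve_ctmc_exact(net, horizon)
        reps = 1200
        counts: dict[tuple, int] = {}
        for rep in range(reps):
            traj = simulate_ssa(net, horizon=horizon, seed=7000 * case + rep, record=False)
            key = tuple(int(v) for v in traj.final_state())
            counts[key] = counts.get(key, 0) + 1
        from transposim.cli import _chi_square_pvalue

        assert _chi_square_pvalue(snap, counts, reps) > 0.01


class TestFirstPassage:
    def test_pure_death_exponential(self, plasmid_genome, scd_wt):
        # single capture channel at rate k from the bound state: engineer by
        # k_unbind=0 and huge k_bind so binding is instantaneous
        k = 0.05
        rates = RateConstants(k_bind=1e12, k_unbind=0.0, k_synapsis=k, k_post=0.0)
        net = build_network(PathwayKind.S_NEC, rates, plasmid_genome, scd_wt, 1)
        fp = sample_first_passage(net, _pec_predicate(net), reps=1000, seed=9, horizon=1e4)
        assert fp.censoring_fraction == 0.0
        assert abs(fp.mean - 1.0 / k) < 3 * fp.se

    def test_g462d_all_censored(self, tn5_rates, plasmid_genome):
        mutant = MutantSpec(
            architecture=Architecture.SINGLE_CHAIN_DIMER,
            subunit_b_interface=InterfaceAllele.G462D,
        )
        net = build_network(PathwayKind.S_NEC, tn5_rates, plasmid_genome, mutant, 10)
        fp = sample_first_passage(net, _pec_predicate(net), reps=50, seed=2, horizon=100.0)
        assert fp.censoring_fraction == 1.0
        assert fp.times.size == 0

    def test_single_rep_reproducible(self, simple_rates, scd_wt, plasmid_genome):
        net = build_network(PathwayKind.S_NEC, simple_rates, plasmid_genome, scd_wt, 3)
        a = sample_first_passage(net, _pec_predicate(net), reps=1, seed=5, horizon=1e4)
        b = sample_first_passage(net, _pec_predicate(net), reps=1, seed=5, horizon=1e4)
        assert a.times.tolist() == b.times.tolist()

    def test_mean_field_agrees_with_ssa_at_large_counts(self, plasmid_genome, scd_wt):
        # >= 100 copies of every reactant: compare species means at horizon
        rates = RateConstants(k_bind=5e5, k_unbind=0.05, k_synapsis=0.0, k_post=0.0)
        genome = GenomeContext(genome_length_bp=4000, n_elements=100)
        net = build_network(PathwayKind.S_NEC, rates, genome, scd_wt, 400)
        horizon = 30.0
        mf = integrate_mean_field(net, horizon, grid=[0.0, horizon])
        sums = np.zeros(len(net.species))
        reps = 200
        for rep in range(reps):
            traj = simulate_ssa(net, horizon=horizon, seed=300 + rep, record=False)
            sums += traj.final_state()
        ssa_mean = sums / reps
        mf_final = mf.final_state()
        idx = net.species_index("P")
        assert ssa_mean[idx] == pytest.approx(mf_final[idx], rel=0.05)
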