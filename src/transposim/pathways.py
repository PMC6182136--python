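"""Reaction-network builders for the two transpososome assembly pathways.

Species bookkeeping
-------------------
Each transposon element ``i`` is tracked through six states::

    E{i}:FF   both ends free
    E{i}:BF   left end bound, right end free
    E{i}:FB   left end free, right end bound
    E{i}:BB   both ends bound (the blocked state in S-NEC)
    E{i}:PEC  paired-ends complex (synapsis committed)
    E{i}:DONE absorbing post-reaction state

Free protein binding units are species ``P`` (a pre-formed dimer for the
dimeric architectures, a monomer for S-PD), with ``P_mono`` holding the
products of natural-dimer subunit dissociation and ``NS_free`` /
``NS_bound`` the non-specific genomic sites.

In the S-NEC pathway synapsis ("capture") proceeds from the singly occupied
states only: an element with both ends occupied has no naked end left to
recruit and can exit that state only by unbinding.  In S-PD synapsis
requires both ends occupied, because the two end-bound proteins must
dimerize.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

from .model_core import (
    AVOGADRO,
    ActiveSite,
    Architecture,
    GenomeContext,
    InterfaceAllele,
    MutantSpec,
    RateConstants,
)

__all__ = [
    "PathwayKind",
    "ElementState",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "apply_mutant",
    "predict_cleavage_products",
    "interface_competence_probability",
    "CleavagePrediction",
]


class PathwayKind(str, Enum):
    S_NEC = "S_NEC"
    S_PD = "S_PD"
    DOUBLE_DIMER_SPD = "DOUBLE_DIMER_SPD"


class ElementState(str, Enum):
    FREE_FREE = "FF"
    BOUND_FREE = "BF"
    FREE_BOUND = "FB"
    BOUND_BOUND = "BB"
    PEC = "PEC"
    DONE = "DONE"


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action channel.

    ``rate`` is the stochastic rate constant: for a bimolecular channel the
    macroscopic constant has already been divided by ``N_A * V``.  Several
    micro-reactions may share a ``label`` (e.g. "bind-L" covers binding of
    the left end from both the FF and the FB state); labels are the
    channel-level identity used in trajectories and channel counting.
    """

    label: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float
    rate_name: str

    def __post_init__(self) -> None:
        for _, stoich in self.reactants + self.products:
            if stoich < 0:
                raise ValueError("stoichiometries must be non-negative")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


@dataclass
class ReactionNetwork:
    """Species, initial counts, and reaction channels for one configuration."""

    species: list[str]
    initial_counts: list[int]
    reactions: list[Reaction]
    pathway: PathwayKind
    genome: GenomeContext
    mutant: MutantSpec
    rates: RateConstants
    transposase_count: int
    subunit_weights: dict[str, int] = field(default_factory=dict)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    @property
    def channel_labels(self) -> list[str]:
        """Distinct channel labels, in first-appearance order."""
        seen: list[str] = []
        for rxn in self.reactions:
            if rxn.label not in seen:
                seen.append(rxn.label)
        return seen

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def element_species(self, state: ElementState) -> list[str]:
        suffix = ":" + state.value
        return [s for s in self.species if s.startswith("E") and s.endswith(suffix)]

    def net_change(self, rxn: Reaction) -> dict[str, int]:
        delta: dict[str, int] = {}
        for name, stoich in rxn.reactants:
            delta[name] = delta.get(name, 0) - stoich
        for name, stoich in rxn.products:
            delta[name] = delta.get(name, 0) + stoich
        return {k: v for k, v in delta.items() if v != 0}

    def conservation_defect(self, rxn: Reaction) -> tuple[int, int]:
        """(subunit defect, element defect) of one reaction; both must be 0."""
        delta = self.net_change(rxn)
        subunits = sum(self.subunit_weights.get(name, 0) * dv for name, dv in delta.items())
        elements = sum(dv for name, dv in delta.items() if name.startswith("E"))
        return subunits, elements

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway.value,
            "transposase_count": self.transposase_count,
            "species": list(self.species),
            "initial_counts": list(self.initial_counts),
            "n_channels": self.n_channels,
            "channel_labels": self.channel_labels,
            "reactions": [
                {
                    "label": r.label,
                    "reactants": {k: v for k, v in r.reactants},
                    "products": {k: v for k, v in r.products},
                    "rate": r.rate,
                    "rate_name": r.rate_name,
                }
                for r in self.reactions
            ],
            "genome": {
                "genome_length_bp": self.genome.genome_length_bp,
                "n_elements": self.genome.n_elements,
                "volume_liters": self.genome.volume_liters,
                "cis_acting": self.genome.cis_acting,
                "nonspecific_site_spacing_bp": self.genome.nonspecific_site_spacing_bp,
            },
            "mutant": {
                "architecture": self.mutant.architecture.value,
                "subunit_a_active_site": self.mutant.subunit_a_active_site.value,
                "subunit_b_active_site": (
                    self.mutant.subunit_b_active_site.value
                    if self.mutant.subunit_b_active_site
                    else None
                ),
                "subunit_a_interface": self.mutant.subunit_a_interface.value,
                "subunit_b_interface": (
                    self.mutant.subunit_b_interface.value
                    if self.mutant.subunit_b_interface
                    else None
                ),
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _binding_unit_subunits(pathway: PathwayKind, mutant: MutantSpec) -> int:
    """Polypeptide subunits carried by one free binding unit."""
    if pathway is PathwayKind.S_NEC:
        return 2
    if mutant.architecture is Architecture.SINGLE_CHAIN_DIMER:
        return 2
    return 1


def interface_competence_probability(mutant: MutantSpec, engagement_bias: float = 0.5) -> float:
    """Probability that an assembling complex has functional interfaces.

    For the S-NEC single-chain dimer both subunits of the one engaged
    protein contribute to the synaptic interface, so a single G462D subunit
    is fatal.  For the double-dimer S-PD hypothesis each end is engaged by
    one randomly chosen subunit of a separate single-chain dimer and only
    the engaged subunit contributes its interface.
    """
    if not 0.0 <= engagement_bias <= 1.0:
        raise ValueError("engagement_bias must lie in [0, 1]")
    alleles = (mutant.subunit_a_interface, mutant.subunit_b_interface)
    if mutant.architecture is Architecture.MONOMER:
        return 0.0 if mutant.subunit_a_interface is InterfaceAllele.G462D else 1.0
    p_engaged_wt = 0.0
    if alleles[0] is InterfaceAllele.WT:
        p_engaged_wt += engagement_bias
    if alleles[1] is InterfaceAllele.WT:
        p_engaged_wt += 1.0 - engagement_bias
    return p_engaged_wt * p_engaged_wt


def build_network(
    pathway: PathwayKind,
    rates: RateConstants,
    genome: GenomeContext,
    mutant: MutantSpec,
    transposase_count: int,
) -> ReactionNetwork:
    """Construct the reaction network for one pathway / genome / mutant.

    ``transposase_count`` counts free protein binding units: pre-formed
    dimers for S-NEC (and the double-dimer variant), monomers for S-PD.

    Raises
    ------
    ValueError
        For inconsistent pathway/architecture combinations or negative
        counts.
    """
    if transposase_count < 0:
        raise ValueError("transposase_count must be >= 0")
    if pathway is PathwayKind.DOUBLE_DIMER_SPD and mutant.architecture is not (
        Architecture.SINGLE_CHAIN_DIMER
    ):
        raise ValueError("DOUBLE_DIMER_SPD requires SINGLE_CHAIN_DIMER architecture")
    if pathway is PathwayKind.S_NEC and mutant.architecture is Architecture.MONOMER:
        raise ValueError("S_NEC requires a dimeric architecture")

    unit_subunits = _binding_unit_subunits(pathway, mutant)
    na_v = AVOGADRO * genome.volume_liters
    c_bind = rates.k_bind / na_v
    c_ns = rates.k_ns_bind / na_v

    per_element_pools = genome.cis_acting and genome.n_elements > 1
    species: list[str] = []
    counts: list[int] = []
    weights: dict[str, int] = {}

    def add_species(name: str, count: int, weight: int) -> None:
        species.append(name)
        counts.append(count)
        weights[name] = weight

    pools: list[str] = []
    if per_element_pools:
        for i in range(genome.n_elements):
            add_species(f"P{i}", transposase_count, unit_subunits)
            pools.append(f"P{i}")
    else:
        add_species("P", transposase_count, unit_subunits)
        pools = ["P"] * max(genome.n_elements, 1)

    state_weight = {
        ElementState.FREE_FREE: 0,
        ElementState.BOUND_FREE: unit_subunits,
        ElementState.FREE_BOUND: unit_subunits,
        ElementState.BOUND_BOUND: 2 * unit_subunits,
    }
    if pathway is PathwayKind.S_NEC:
        # one dimer spans both ends of the synapse
        pec_weight = unit_subunits
    else:
        pec_weight = 2 * unit_subunits
    for i in range(genome.n_elements):
        add_species(f"E{i}:FF", 1, 0)
        add_species(f"E{i}:BF", 0, state_weight[ElementState.BOUND_FREE])
        add_species(f"E{i}:FB", 0, state_weight[ElementState.FREE_BOUND])
        add_species(f"E{i}:BB", 0, state_weight[ElementState.BOUND_BOUND])
        add_species(f"E{i}:PEC", 0, pec_weight)
        add_species(f"E{i}:DONE", 0, pec_weight)

    include_ns = (
        not genome.cis_acting and rates.k_ns_bind > 0 and genome.n_nonspecific_sites > 0
    )
    if include_ns:
        # start the pool at the non-specific binding equilibrium: in a cell
        # the transposase is pre-equilibrated with genomic DNA, and starting
        # all-free would let the ends be found at the unsequestered rate
        # during the relaxation transient
        n_sites = genome.n_nonspecific_sites
        ns_bound0 = 0
        if rates.k_ns_unbind > 0:
            site_conc = n_sites / na_v
            occ = rates.k_ns_bind * site_conc / (
                rates.k_ns_bind * site_conc + rates.k_ns_unbind
            )
            ns_bound0 = int(round(transposase_count * occ))
        pool_idx = species.index(pools[0])
        counts[pool_idx] -= ns_bound0
        add_species("NS_free", n_sites - ns_bound0, 0)
        add_species("NS_bound", ns_bound0, unit_subunits)

    natural_dimer = (
        pathway is PathwayKind.S_NEC
        and mutant.architecture is Architecture.NATURAL_DIMER
        and rates.k_multimer_dissoc > 0
    )
    if natural_dimer:
        add_species("P_mono", 0, 1)

    synapsis_allowed = not mutant.interface_dead
    if pathway is PathwayKind.DOUBLE_DIMER_SPD:
        # each engaged subunit contributes one half of the synaptic interface
        k_syn = rates.k_synapsis * interface_competence_probability(mutant)
        synapsis_allowed = k_syn > 0
    elif pathway is PathwayKind.S_NEC:
        k_syn = rates.effective_synapsis
    else:
        k_syn = rates.k_synapsis

    reactions: list[Reaction] = []

    def rxn(label, reactants, products, rate, rate_name):
        reactions.append(
            Reaction(
                label=label,
                reactants=tuple(reactants),
                products=tuple(products),
                rate=rate,
                rate_name=rate_name,
            )
        )

    for i in range(genome.n_elements):
        pool = pools[i] if pools else "P"
        ff, bf, fb, bb = (f"E{i}:{s}" for s in ("FF", "BF", "FB", "BB"))
        pec, done = f"E{i}:PEC", f"E{i}:DONE"
        rxn("bind-L", [(pool, 1), (ff, 1)], [(bf, 1)], c_bind, "k_bind")
        rxn("bind-L", [(pool, 1), (fb, 1)], [(bb, 1)], c_bind, "k_bind")
        rxn("bind-R", [(pool, 1), (ff, 1)], [(fb, 1)], c_bind, "k_bind")
        rxn("bind-R", [(pool, 1), (bf, 1)], [(bb, 1)], c_bind, "k_bind")
        rxn("unbind-L", [(bf, 1)], [(ff, 1), (pool, 1)], rates.k_unbind, "k_unbind")
        rxn("unbind-L", [(bb, 1)], [(fb, 1), (pool, 1)], rates.k_unbind, "k_unbind")
        rxn("unbind-R", [(fb, 1)], [(ff, 1), (pool, 1)], rates.k_unbind, "k_unbind")
        rxn("unbind-R", [(bb, 1)], [(bf, 1), (pool, 1)], rates.k_unbind, "k_unbind")
        if synapsis_allowed:
            if pathway is PathwayKind.S_NEC:
                # naked-end capture: only a singly occupied element has a
                # free partner end to recruit; BB is the blocked state
                rxn("capture", [(bf, 1)], [(pec, 1)], k_syn, "k_synapsis")
                rxn("capture", [(fb, 1)], [(pec, 1)], k_syn, "k_synapsis")
            else:
                rxn("synapse", [(bb, 1)], [(pec, 1)], k_syn, "k_synapsis")
        rxn("complete", [(pec, 1)], [(done, 1)], rates.k_post, "k_post")

    if include_ns:
        for pool in dict.fromkeys(pools):
            rxn(
                "ns-bind",
                [(pool, 1), ("NS_free", 1)],
                [("NS_bound", 1)],
                c_ns,
                "k_ns_bind",
            )
            rxn(
                "ns-unbind",
                [("NS_bound", 1)],
                [(pool, 1), ("NS_free", 1)],
                rates.k_ns_unbind,
                "k_ns_unbind",
            )
    if natural_dimer:
        rxn(
            "multimer-dissoc",
            [("P", 1)],
            [("P_mono", 2)],
            rates.k_multimer_dissoc,
            "k_multimer_dissoc",
        )

    return ReactionNetwork(
        species=species,
        initial_counts=counts,
        reactions=reactions,
        pathway=pathway,
        genome=genome,
        mutant=mutant,
        rates=rates,
        transposase_count=transposase_count,
        subunit_weights=weights,
    )


def apply_mutant(network: ReactionNetwork, mutant: MutantSpec) -> ReactionNetwork:
    """Rebuild a network's channels under a (possibly different) mutant.

    G462D in any subunit removes the synapsis channel (S-NEC capture, or
    scales the double-dimer synapsis by the interface-competence
    probability).  Active-site (ADE) mutations leave the assembly channels
    untouched; they only alter the cleavage-product map, which is computed
    by :func:`predict_cleavage_products`.
    """
    return build_network(
        network.pathway,
        network.rates,
        network.genome,
        mutant,
        network.transposase_count,
    )


PRODUCT_CLASSES = ("UNCUT", "SINGLE_END_CUT", "DOUBLE_END_CUT")


@dataclass(frozen=True)
class CleavagePrediction:
    """Product-class distribution among assembled complexes, plus activity.

    ``products`` conditions on an assembled (interface-competent)
    transpososome; ``relative_activity`` multiplies the assembly probability
    by the fraction of assembled complexes that proceed to completion
    (double-end cleavage).
    """

    products: dict[str, float]
    relative_activity: float
    assembly_probability: float

    def __post_init__(self) -> None:
        total = sum(self.products.values())
        if self.products and abs(total - 1.0) > 1e-9:
            raise ValueError("product probabilities must sum to 1")


def predict_cleavage_products(
    mutant: MutantSpec,
    pathway: PathwayKind,
    engagement_bias: float = 0.5,
) -> CleavagePrediction:
    """Predict cleavage-product classes and relative activity for a mutant.

    Within a formed complex each transposon end is cut iff the subunit
    engaged at that end has a functional DDE active site.  For the S-NEC
    single-chain dimer the two subunits of one protein engage the two ends
    (one each).  For the hypothetical double-dimer S-PD pathway each end is
    engaged by one randomly chosen subunit (``engagement_bias`` is the
    probability of choosing subunit A) of a separate single-chain dimer,
    and the complex assembles only if both engaged, interface-contributing
    subunits are wild type.
    """
    if not 0.0 <= engagement_bias <= 1.0:
        raise ValueError("engagement_bias must lie in [0, 1]")

    def empty(assembly: float) -> CleavagePrediction:
        return CleavagePrediction(
            products={"UNCUT": 1.0, "SINGLE_END_CUT": 0.0, "DOUBLE_END_CUT": 0.0},
            relative_activity=0.0,
            assembly_probability=assembly,
        )

    if mutant.architecture is Architecture.MONOMER:
        if pathway is not PathwayKind.S_PD:
            raise ValueError("monomeric transposase assembles via S_PD only")
        if mutant.subunit_a_interface is InterfaceAllele.G462D:
            return empty(0.0)
        cut = 1.0 if mutant.subunit_a_active_site is ActiveSite.DDE else 0.0
        products = {
            "UNCUT": (1 - cut) * (1 - cut),
            "SINGLE_END_CUT": 2 * cut * (1 - cut),
            "DOUBLE_END_CUT": cut * cut,
        }
        return CleavagePrediction(
            products=products,
            relative_activity=products["DOUBLE_END_CUT"],
            assembly_probability=1.0,
        )

    cut_a = 1.0 if mutant.subunit_a_active_site is ActiveSite.DDE else 0.0
    cut_b = 1.0 if mutant.subunit_b_active_site is ActiveSite.DDE else 0.0

    if pathway is PathwayKind.S_NEC:
        assembly = 0.0 if mutant.interface_dead else 1.0
        if assembly == 0.0:
            return empty(0.0)
        # subunit A at one end, subunit B at the other, deterministically
        p_double = cut_a * cut_b
        p_uncut = (1 - cut_a) * (1 - cut_b)
        p_single = 1.0 - p_double - p_uncut
    elif pathway is PathwayKind.DOUBLE_DIMER_SPD:
        assembly = interface_competence_probability(mutant, engagement_bias)
        if assembly == 0.0:
            return empty(0.0)
        # condition the engaged-subunit identity on a WT interface
        wt_weight = 0.0
        p_cut_given_wt = 0.0
        if mutant.subunit_a_interface is InterfaceAllele.WT:
            wt_weight += engagement_bias
            p_cut_given_wt += engagement_bias * cut_a
        if mutant.subunit_b_interface is InterfaceAllele.WT:
            wt_weight += 1.0 - engagement_bias
            p_cut_given_wt += (1.0 - engagement_bias) * cut_b
        p_cut = p_cut_given_wt / wt_weight
        p_double = p_cut * p_cut
        p_uncut = (1 - p_cut) * (1 - p_cut)
        p_single = 2 * p_cut * (1 - p_cut)
    else:
        raise ValueError(f"unsupported pathway for a dimeric mutant: {pathway}")

    products = {
        "UNCUT": p_uncut,
        "SINGLE_END_CUT": p_single,
        "DOUBLE_END_CUT": p_double,
    }
    return CleavagePrediction(
        products=products,
        relative_activity=assembly * p_double,
        assembly_probability=assembly,
    )
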