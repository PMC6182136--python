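"""Parameter types, unit conversions and closed-form kinetic arithmetic.

All internal times are seconds and all concentrations molar.  Conversions to
integer molecule counts happen only at the boundary, via
:func:`concentration_to_count`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "AVOGADRO",
    "RateConstants",
    "GenomeContext",
    "MutantSpec",
    "Architecture",
    "ActiveSite",
    "InterfaceAllele",
    "ArchetypeName",
    "half_life_to_rate",
    "rate_to_half_life",
    "nonspecific_site_excess",
    "orders_of_magnitude_ratio",
    "concentration_to_count",
    "count_to_concentration",
]

AVOGADRO = 6.02214076e23  # mol^-1, CODATA 2018 exact


class Architecture(str, Enum):
    """Subunit architecture of the transposase protein."""

    MONOMER = "MONOMER"
    SINGLE_CHAIN_DIMER = "SINGLE_CHAIN_DIMER"
    NATURAL_DIMER = "NATURAL_DIMER"


class ActiveSite(str, Enum):
    """Catalytic triad state of one subunit (DDE functional, ADE dead)."""

    DDE = "DDE"
    ADE = "ADE"


class InterfaceAllele(str, Enum):
    """Dimerization-interface allele of one subunit."""

    WT = "WT"
    G462D = "G462D"


class ArchetypeName(str, Enum):
    """Named parameter archetypes shipped with the package."""

    TN5_MONOMER = "TN5_MONOMER"
    TN5_SCD = "TN5_SCD"
    HSMAR1 = "HSMAR1"


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of the transpososome assembly model.

    Parameters
    ----------
    k_bind : float
        Association rate constant for transposase--end binding (M^-1 s^-1).
    k_unbind : float
        Dissociation rate constant of the single-end complex (s^-1).
    k_synapsis : float
        Synapsis rate constant (s^-1); unimolecular capture of the tethered
        partner end (S-NEC) or dimerization of the two end-bound proteins
        (S-PD).
    k_post : float
        Lumped rate constant for every step after synapsis (s^-1).
    k_ns_bind : float, optional
        Non-specific DNA association rate constant (M^-1 s^-1).
    k_ns_unbind : float, optional
        Non-specific DNA dissociation rate constant (s^-1).
    k_multimer_dissoc : float, optional
        Subunit dissociation rate of a pre-formed transposase multimer
        (s^-1); relevant for natural dimers only.
    synapsis_attenuation : float, optional
        Dimensionless factor in (0, 1] multiplying ``k_synapsis`` after
        single-end binding (conformational-change penalty).
    """

    k_bind: float
    k_unbind: float
    k_synapsis: float
    k_post: float
    k_ns_bind: float = 0.0
    k_ns_unbind: float = 0.0
    k_multimer_dissoc: float = 0.0
    synapsis_attenuation: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k_bind",
            "k_unbind",
            "k_synapsis",
            "k_post",
            "k_ns_bind",
            "k_ns_unbind",
            "k_multimer_dissoc",
        ):
            value = getattr(self, name)
            if not (value >= 0.0) or math.isnan(value):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not (0.0 < self.synapsis_attenuation <= 1.0):
            raise ValueError(
                "synapsis_attenuation must lie in (0, 1], got "
                f"{self.synapsis_attenuation!r}"
            )

    @property
    def effective_synapsis(self) -> float:
        """Synapsis rate after the single-end attenuation factor."""
        return self.k_synapsis * self.synapsis_attenuation

    def with_(self, **changes) -> "RateConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class GenomeContext:
    """Genomic context in which the reaction takes place."""

    genome_length_bp: int
    n_elements: int = 1
    volume_liters: float = 1e-15
    cis_acting: bool = False
    nonspecific_site_spacing_bp: int = 1

    def __post_init__(self) -> None:
        if self.n_elements < 0:
            raise ValueError("n_elements must be >= 0")
        if self.genome_length_bp < 2 * self.n_elements:
            raise ValueError(
                "genome_length_bp must be >= 2 * n_elements "
                f"({self.genome_length_bp} < {2 * self.n_elements})"
            )
        if not self.volume_liters > 0:
            raise ValueError("volume_liters must be > 0")
        if self.nonspecific_site_spacing_bp < 1:
            raise ValueError("nonspecific_site_spacing_bp must be >= 1")

    @property
    def n_nonspecific_sites(self) -> int:
        """Number of candidate non-specific binding sites."""
        return self.genome_length_bp // self.nonspecific_site_spacing_bp

    @property
    def end_concentration(self) -> float:
        """Molar concentration of transposon ends (two per element)."""
        return count_to_concentration(2 * self.n_elements, self.volume_liters)


@dataclass(frozen=True)
class MutantSpec:
    """Mutant composition of the transposase.

    For a ``MONOMER`` architecture only the ``subunit_a_*`` fields are
    meaningful and the ``subunit_b_*`` fields must be left unset (``None``).
    """

    architecture: Architecture = Architecture.MONOMER
    subunit_a_active_site: ActiveSite = ActiveSite.DDE
    subunit_b_active_site: ActiveSite | None = None
    subunit_a_interface: InterfaceAllele = InterfaceAllele.WT
    subunit_b_interface: InterfaceAllele | None = None

    def __post_init__(self) -> None:
        if self.architecture is Architecture.MONOMER:
            if self.subunit_b_active_site is not None or self.subunit_b_interface is not None:
                raise ValueError(
                    "MONOMER architecture uses only subunit_a fields; "
                    "subunit_b fields must be unset"
                )
        else:
            object.__setattr__(
                self,
                "subunit_b_active_site",
                self.subunit_b_active_site or ActiveSite.DDE,
            )
            object.__setattr__(
                self,
                "subunit_b_interface",
                self.subunit_b_interface or InterfaceAllele.WT,
            )

    @classmethod
    def wild_type(cls, architecture: Architecture = Architecture.MONOMER) -> "MutantSpec":
        return cls(architecture=architecture)

    @property
    def interface_dead(self) -> bool:
        """True when any subunit carries the dimerization-dead allele."""
        if self.subunit_a_interface is InterfaceAllele.G462D:
            return True
        return self.subunit_b_interface is InterfaceAllele.G462D

    @property
    def active_sites(self) -> tuple[ActiveSite, ...]:
        if self.architecture is Architecture.MONOMER:
            return (self.subunit_a_active_site,)
        return (self.subunit_a_active_site, self.subunit_b_active_site)


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant from a half-life: ``k = ln(2) / t_half``."""
    if not t_half > 0:
        raise ValueError(f"t_half must be > 0, got {t_half!r}")
    return math.log(2.0) / t_half


def rate_to_half_life(rate: float) -> float:
    """Inverse of :func:`half_life_to_rate`."""
    if not rate > 0:
        raise ValueError(f"rate must be > 0, got {rate!r}")
    return math.log(2.0) / rate


def nonspecific_site_excess(
    dna_length_bp: int, n_specific_ends: int, spacing_bp: int = 1
) -> float:
    """Fold excess of candidate non-specific sites over specific ends.

    ``floor(dna_length_bp / spacing_bp) / n_specific_ends``
    """
    if n_specific_ends < 1:
        raise ValueError("n_specific_ends must be >= 1")
    if spacing_bp < 1:
        raise ValueError("spacing_bp must be >= 1")
    if dna_length_bp < spacing_bp:
        raise ValueError("dna_length_bp must be >= spacing_bp")
    return (dna_length_bp // spacing_bp) / n_specific_ends


def orders_of_magnitude_ratio(a: float, b: float) -> float:
    """``log10(a / b)`` for positive a and b."""
    if not a > 0 or not b > 0:
        raise ValueError("both arguments must be > 0")
    return math.log10(a / b)


def concentration_to_count(conc: float, volume: float) -> int:
    """Molecule count from a molar concentration in a given volume.

    Rounds to the nearest integer (halves away from zero).
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if not volume > 0:
        raise ValueError("volume must be > 0")
    return int(math.floor(conc * AVOGADRO * volume + 0.5))


def count_to_concentration(count: float, volume: float) -> float:
    """Molar concentration of `count` molecules in `volume` liters."""
    if not volume > 0:
        raise ValueError("volume must be > 0")
    return count / (AVOGADRO * volume)
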