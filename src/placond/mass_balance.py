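"""Initial-charge accounting for solution polycondensation of lactic acid.

Commercial lactic acid is hygroscopic and arrives as a concentrated aqueous
solution; before polymerization the charge is azeotropically dried, during
which part of the acid cyclizes to lactide (inert under the mild reaction
conditions modeled here) and part condenses to short oligomers, each step
releasing water.  The functions in this module turn the weighed masses of
that pre-history — commercial acid, water collected in the receiver,
lactide conversion — into bounded estimates of the *dry* lactic-acid mass
actually available for chain growth, and from a chosen mass into the
initial concentrations of the condensed kinetic model: chain-end bond
concentration ``a0``, ester bonds ``c0`` (zero at the start), trace water
``w0``, and the (constant) solvent and catalyst concentrations ``S`` and
``C``.

Three dry-mass scenarios bracket the uncertainty left by the side
reactions:

* **upper** — residual water removed, nothing else corrected;
* **intermediate** — additionally corrected for the lactide conversion;
* **lower** — additionally corrected for early oligomerization, counted as
  an *effective* mole number (acid moles minus oligomer-water moles) so
  that the reactive-bond budget of the real acid/oligomer mixture is
  preserved.

Concentrations are nominal room-temperature values: the liquid volume is
computed from the solvent mass and a configurable solvent density.  Any
fixed volume convention rescales all concentrations uniformly and is
absorbed by the fitted rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "MassLedger",
    "InitialState",
    "reference_ledger",
    "lactide_corrected_mass",
    "oligomer_water",
    "effective_la_mass_lower",
    "dry_mass_scenarios",
    "initial_concentrations",
    "initial_water_mole_fraction",
]

#: Default repeat-unit formal weight of the polyester, g/mol.
FW_MONO = 72.06

#: Hard ceiling on the admissible initial water mole fraction; the drying
#: protocol leaves at most ~10 ppm of water, so anything within orders of
#: magnitude of 1e-3 signals a unit error in the input.
XW0_LIMIT = 1e-3


@dataclass(frozen=True)
class MassLedger:
    """Masses, molar masses and weight ratios describing the reactor charge.

    All masses in grams, molar masses in g/mol, density in g/mL; the two
    weight fractions are the acid:solvent and catalyst:acid ratios of the
    charge recipe.
    """

    m_dry_la_upper: float
    lactide_wt_frac: float
    m_total_water_removed: float
    m_residual_water: float
    m_lactide_water: float
    mw_la: float = 90.08
    mw_water: float = 18.0
    mw_solvent: float = 92.14          # toluene
    mw_catalyst: float = 405.12        # tin(II) 2-ethylhexanoate
    la_wt_frac_vs_solvent: float = 0.584
    cat_wt_frac_vs_la: float = 0.0056
    solvent_density: float = 0.867     # toluene, room temperature

    def __post_init__(self) -> None:
        for name in (
            "m_dry_la_upper",
            "m_total_water_removed",
            "mw_la",
            "mw_water",
            "mw_solvent",
            "mw_catalyst",
            "solvent_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("m_residual_water", "m_lactide_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("lactide_wt_frac", "la_wt_frac_vs_solvent", "cat_wt_frac_vs_la"):
            frac = getattr(self, name)
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.m_residual_water + self.m_lactide_water > self.m_total_water_removed:
            raise ValueError(
                "inconsistent ledger: residual + lactide water exceeds total water removed"
            )


@dataclass(frozen=True)
class InitialState:
    """Initial concentrations (mol/L) of the condensed kinetic model.

    ``a0`` is the chain-end bond-pair concentration (equal to the monomer
    concentration at t=0), ``c0`` the ester-bond concentration (normally 0),
    ``w0`` the trace water left after drying; ``S`` and ``C`` are the
    solvent and catalyst concentrations, held constant by the model.
    """

    a0: float
    c0: float
    w0: float
    S: float
    C: float
    fw_mono: float = FW_MONO
    volume: float = 0.0  # liquid volume, L (informational)

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be strictly positive")
        if self.c0 < 0 or self.w0 < 0:
            raise ValueError("c0 and w0 must be nonnegative")
        if self.S <= 0:
            raise ValueError("S must be strictly positive")
        if self.C < 0:
            raise ValueError("C must be nonnegative")

    def with_(self, **kwargs) -> "InitialState":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def reference_ledger() -> MassLedger:
    """The optimal-run charge: 7.11 g dry acid after removing 0.93 g residual
    water, 1.2 g total water collected, 5 wt.% lactide conversion with
    0.0355 g of associated water, 58.4 wt.% acid vs toluene and 0.56 wt.%
    catalyst vs acid."""
    return MassLedger(
        m_dry_la_upper=7.11,
        lactide_wt_frac=0.05,
        m_total_water_removed=1.2,
        m_residual_water=0.93,
        m_lactide_water=0.0355,
    )


def lactide_corrected_mass(m_dry: float, lactide_wt_frac: float) -> float:
    """Dry acid mass after removing the fraction converted to (inert) lactide."""
    if m_dry < 0:
        raise ValueError("mass must be nonnegative")
    if not 0.0 <= lactide_wt_frac < 1.0:
        raise ValueError("lactide_wt_frac must lie in [0, 1)")
    return m_dry * (1.0 - lactide_wt_frac)


def oligomer_water(
    m_total_removed: float, m_residual: float, m_lactide_water: float
) -> float:
    """Water attributable to early oligomerization: total collected minus
    residual minus lactide-formation water."""
    if min(m_total_removed, m_residual, m_lactide_water) < 0:
        raise ValueError("masses must be nonnegative")
    out = m_total_removed - m_residual - m_lactide_water
    if out < 0:
        raise ValueError(
            "inconsistent ledger: residual + lactide water exceeds total removed"
        )
    return out


def effective_la_mass_lower(
    m_dry_upper: float,
    m_lactide_consumed_la: float,
    m_olig_water: float,
    mw_la: float = 90.08,
    mw_water: float = 18.0,
) -> float:
    """Lower-bound dry acid mass counting *effective* reactive-bond moles.

    Early oligomerization of n_p monomers releases (n_p - 1) waters and
    leaves a species with a single pair of reactive end groups, so the
    mixture of acid and oligomers carries the same reactive-bond budget as
    ``n_LA - n_water`` monomers.  The mass returned is that effective mole
    number expressed as grams of monomer.
    """
    if min(m_dry_upper, m_lactide_consumed_la, m_olig_water) < 0:
        raise ValueError("masses must be nonnegative")
    if m_dry_upper <= m_lactide_consumed_la:
        raise ValueError("lactide-consumed mass must be below the dry upper bound")
    moles = (m_dry_upper - m_lactide_consumed_la) / mw_la - m_olig_water / mw_water
    if moles < 0:
        # tolerate cancellation noise when the two mole counts tie exactly
        if moles > -1e-12 * (m_dry_upper / mw_la):
            return 0.0
        raise ValueError("inconsistent ledger: negative effective mole number")
    return moles * mw_la


def dry_mass_scenarios(ledger: MassLedger) -> dict[str, float]:
    """The three bounded dry-acid masses (g) implied by the ledger."""
    upper = ledger.m_dry_la_upper
    intermediate = lactide_corrected_mass(upper, ledger.lactide_wt_frac)
    lower = effective_la_mass_lower(
        upper,
        upper * ledger.lactide_wt_frac,
        oligomer_water(
            ledger.m_total_water_removed,
            ledger.m_residual_water,
            ledger.m_lactide_water,
        ),
        ledger.mw_la,
        ledger.mw_water,
    )
    return {"lower": lower, "intermediate": intermediate, "upper": upper}


def initial_concentrations(
    ledger: MassLedger,
    m_dry_la: float,
    xw0: float = 1e-5,
    fw_mono: float = FW_MONO,
) -> InitialState:
    """Initial concentrations for a given dry-acid mass and water mole fraction.

    The solvent mass follows from the acid:solvent weight ratio, the liquid
    volume from the solvent mass and density, and ``w0`` inverts the
    initial-state mole-fraction definition
    ``xw0 = w0 / (S + C + a0 + w0)``, i.e.
    ``w0 = xw0 (S + C + a0) / (1 - xw0)``.

    ``xw0`` must be positive (an exactly dry mixture cannot depolymerize at
    all and is not a physical start) and below 1e-3, orders of magnitude
    above the <= 10 ppm regime the drying protocol achieves.
    """
    if m_dry_la <= 0:
        raise ValueError("m_dry_la must be strictly positive")
    if not 0.0 < xw0 < XW0_LIMIT:
        raise ValueError(f"xw0 must lie in (0, {XW0_LIMIT:g})")
    m_solvent = m_dry_la / ledger.la_wt_frac_vs_solvent
    volume = m_solvent / ledger.solvent_density / 1000.0  # L
    a0 = (m_dry_la / ledger.mw_la) / volume
    S = (m_solvent / ledger.mw_solvent) / volume
    m_cat = m_dry_la * ledger.cat_wt_frac_vs_la
    C = (m_cat / ledger.mw_catalyst) / volume
    w0 = xw0 * (S + C + a0) / (1.0 - xw0)
    return InitialState(a0=a0, c0=0.0, w0=w0, S=S, C=C, fw_mono=fw_mono, volume=volume)


def initial_water_mole_fraction(init: InitialState) -> float:
    """Water mole fraction of an initial state, ``w0 / (S + C + a0 + w0)``.

    This is the molecule-counting convention used to *construct* ``w0`` (the
    denominator counts solvent, catalyst, monomer and water molecules); the
    running condensed model uses its own bond-counting formula, which differs
    slightly (see :func:`placond.condensed.water_mole_fraction`).
    """
    return init.w0 / (init.S + init.C + init.a0 + init.w0)
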