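"""Equilibrium headspace physics.

The model treats the vapor above a solution in a closed vial as an ideal gas
at equilibrium. For a neat liquid the headspace mass follows directly from
the vapor pressure via PV = nRT:

    mass = VP(atm) * MW * V / (R * T)

For a solution, ideal (Raoult) behavior scales the pure-compound vapor
pressure by the solute mole fraction; the mole fraction is evaluated on a
mass basis per 100 g of solution, which needs no density data and reproduces
the neat limit exactly.

Two constants modes are provided: ``paper_printed`` (R = 0.082 L·atm/K/mol,
0.001316 atm/mmHg — the rounded constants of the worked example this model
reproduces) and ``high_precision`` (R = 0.082057, 1/760). They agree within
0.2 % and ``paper_printed`` is the default so reference values round-trip.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .chem import ChemicalRecord
from .errors import InputError, LoadError

logger = logging.getLogger(__name__)

#: constants_mode -> (R in L·atm/(K·mol), atm per mmHg)
CONSTANTS = {
    "paper_printed": (0.082, 0.001316),
    "high_precision": (0.082057, 1.0 / 760.0),
}

UG_PER_G = 1.0e6


@dataclass(frozen=True)
class HeadspaceScenario:
    """Headspace volume, temperature and gas-constant convention.

    Defaults describe the reference scenario: a 0.1 L (100 mL) headspace at
    298 K sniffed once per day.
    """

    volume_L: float = 0.1
    temperature_K: float = 298.0
    constants_mode: str = "paper_printed"

    def __post_init__(self) -> None:
        if self.volume_L <= 0:
            raise InputError(f"headspace volume must be > 0 L, got {self.volume_L}")
        if self.temperature_K <= 0:
            raise InputError(f"temperature must be > 0 K, got {self.temperature_K}")
        if self.constants_mode not in CONSTANTS:
            raise InputError(f"unknown constants_mode {self.constants_mode!r}")
        if abs(self.temperature_K - 298.0) > 1e-9:
            # VP inputs are defined at 25 degC; other temperatures are inconsistent
            logger.warning(
                "scenario temperature %.1f K != 298 K but vapor pressures are "
                "defined at 25 degC", self.temperature_K,
            )

    @property
    def gas_constant(self) -> float:
        return CONSTANTS[self.constants_mode][0]

    @property
    def mmHg_to_atm(self) -> float:
        return CONSTANTS[self.constants_mode][1]

    def describe(self) -> dict:
        return {
            "volume_L": self.volume_L,
            "temperature_K": self.temperature_K,
            "constants_mode": self.constants_mode,
            "gas_constant": self.gas_constant,
            "mmHg_to_atm": self.mmHg_to_atm,
        }


@dataclass(frozen=True)
class Solvent:
    """A solvent as a list of (molar mass g/mol, mass fraction) components."""

    name: str
    components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        total = sum(frac for _, frac in self.components)
        if abs(total - 1.0) > 1e-9:
            raise InputError(f"solvent {self.name}: mass fractions sum to {total}, not 1")
        if any(mw <= 0 for mw, _ in self.components):
            raise InputError(f"solvent {self.name}: nonpositive component molar mass")

    def moles_per_gram(self) -> float:
        """Moles of solvent per gram of solvent."""
        return sum(frac / mw for mw, frac in self.components)


#: built-in solvents; "50 % ethanol in water" is read as mass-based
SOLVENTS: dict[str, Solvent] = {
    "water": Solvent("water", ((18.02, 1.0),)),
    "propylene_glycol": Solvent("propylene_glycol", ((76.09, 1.0),)),
    "ethanol_water_50_50": Solvent(
        "ethanol_water_50_50", ((46.07, 0.5), (18.02, 0.5))
    ),
}

#: short aliases accepted at the CLI boundary
SOLVENT_ALIASES = {"pg": "propylene_glycol", "etoh50": "ethanol_water_50_50"}


def get_solvent(solvent: str | Solvent) -> Solvent:
    if isinstance(solvent, Solvent):
        return solvent
    key = SOLVENT_ALIASES.get(solvent, solvent)
    try:
        return SOLVENTS[key]
    except KeyError:
        raise InputError(
            f"unknown solvent {solvent!r}; choose from {sorted(SOLVENTS)}"
        ) from None


def headspace_mass(
    vp_mmHg: float, mw: float, scenario: HeadspaceScenario | None = None
) -> float:
    """Equilibrium mass (μg) of a chemical in the headspace above a neat liquid.

    Ideal-gas evaluation of mass = VP·MW·V / (R·T), with VP converted from
    mmHg to atm by the scenario's constants mode. Strictly linear in VP, MW
    and V.
    """
    scenario = scenario or HeadspaceScenario()
    if vp_mmHg < 0:
        raise InputError(f"vapor pressure must be >= 0 mmHg, got {vp_mmHg}")
    if mw <= 0:
        raise InputError(f"molecular weight must be > 0 g/mol, got {mw}")
    atm = vp_mmHg * scenario.mmHg_to_atm
    grams = atm * mw * scenario.volume_L / (scenario.gas_constant * scenario.temperature_K)
    return grams * UG_PER_G


def mole_fraction(conc_pct_ww: float, mw_chemical: float, solvent: str | Solvent) -> float:
    """Mole fraction of the solute in solution at *conc_pct_ww* % w/w.

    Computed per 100 g of solution: n_chem = conc/MW; n_solv sums each solvent
    component's (100 − conc)·mass_fraction / MW. Equals 0 at 0 % and 1 at 100 %.
    """
    if not 0.0 <= conc_pct_ww <= 100.0:
        raise InputError(f"concentration must be in [0, 100] %, got {conc_pct_ww}")
    if mw_chemical <= 0:
        raise InputError(f"molecular weight must be > 0 g/mol, got {mw_chemical}")
    solv = get_solvent(solvent)
    n_chem = conc_pct_ww / mw_chemical
    n_solv = (100.0 - conc_pct_ww) * solv.moles_per_gram()
    if n_chem == 0.0:
        return 0.0
    return n_chem / (n_chem + n_solv)


def partial_pressure(x: float, vp_mmHg: float) -> float:
    """Raoult partial pressure (mmHg): mole fraction times pure-compound VP."""
    if not 0.0 <= x <= 1.0:
        raise InputError(f"mole fraction must be in [0, 1], got {x}")
    if vp_mmHg < 0:
        raise InputError(f"vapor pressure must be >= 0 mmHg, got {vp_mmHg}")
    return x * vp_mmHg


def adjusted_headspace_mass(
    conc_pct_ww: float,
    record: ChemicalRecord,
    solvent: str | Solvent,
    scenario: HeadspaceScenario | None = None,
) -> float:
    """Headspace mass (μg) above a solution of *record* at *conc_pct_ww* % w/w.

    Evaluates the neat-liquid relation at the Raoult partial pressure; equals
    the neat mass at 100 % and zero at 0 %.
    """
    x = mole_fraction(conc_pct_ww, record.mw, solvent)
    return headspace_mass(partial_pressure(x, record.vp_mmHg), record.mw, scenario)


# --- vapor-pressure importer ----------------------------------------------

_VP_SELECTED = re.compile(
    r"^\s*(?:Selected\s+)?VP\s*[:=]?\s*([0-9.Ee+-]+)\s*mm\s*Hg", re.IGNORECASE | re.MULTILINE
)
_VP_EXPERIMENTAL = re.compile(
    r"^\s*Exper(?:imental)?[^\n]*?VP\s*[:=]\s*([0-9.Ee+-]+)\s*mm\s*Hg",
    re.IGNORECASE | re.MULTILINE,
)


def parse_epi_suite_vp(text: str) -> tuple[float, str]:
    """Extract a 25 degC vapor pressure (mmHg) from EPI Suite/MPBPWIN-style text.

    Returns ``(vp_mmHg, source)`` where source is "experimental" when the
    report carries an experimental database value (preferred over the model
    prediction, matching how such reports are normally read) and "predicted"
    otherwise.
    """
    m = _VP_EXPERIMENTAL.search(text)
    if m:
        return float(m.group(1)), "experimental"
    matches = _VP_SELECTED.findall(text)
    if matches:
        # the "Selected/mean" line is last in MPBPWIN output; take the final match
        return float(matches[-1]), "predicted"
    raise LoadError("no vapor-pressure line found in EPI Suite text")
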