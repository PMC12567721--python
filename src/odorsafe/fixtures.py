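"""Deterministic synthetic chemical panels with ground-truth expectations.

Every stage of the pipeline is testable without downloads or external tools:
panels draw structures from a small curated library whose hazard classes
were verified by hand-tracing the shipped Cramer question table during
development (each entry stores its expected traversal path for audit), and
attach vapor pressures drawn log-uniformly over a volatility profile.

The expected screening numbers are produced by a deliberately independent,
straight-line arithmetic oracle embedded here — plain formula evaluation
with its own copies of the constants. This module never imports the hazard,
headspace, screening or validation logic, so agreement between
``screen_batch`` and a panel's expectations is a genuine two-route check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import ChemicalRecord
from .errors import InputError

# oracle constants: an independent copy of the reference scenario
_R = 0.082              # L·atm/(K·mol)
_MMHG_TO_ATM = 0.001316
_VOLUME_L = 0.1
_TEMP_K = 298.0
_WATER_MW = 18.02
_TTC = {"mutagen": 12.0, "cramer_III": 90.0, "cramer_II": 540.0, "cramer_I": 1800.0}

# hand-traced traversal paths through the shipped Cramer question table
_PATH_Q5 = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", True)]
_PATH_OPEN_OK = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                 ("Q7", False), ("Q19", False), ("Q20", True)]
_PATH_OPEN_BAD = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                  ("Q7", False), ("Q19", False), ("Q20", False)]
_PATH_BENZENE_OK = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                    ("Q7", False), ("Q19", True), ("Q6", True)]
_PATH_BENZENE_BAD = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                     ("Q7", False), ("Q19", True), ("Q6", False)]
_PATH_OHET_OK = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                 ("Q7", True), ("Q7A", False), ("Q8", False), ("Q10", True)]
_PATH_OHET_BAD = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                  ("Q7", True), ("Q7A", False), ("Q8", False), ("Q10", False)]
_PATH_HETAROM = [("Q1", False), ("Q2", False), ("Q3", False), ("Q5", False),
                 ("Q7", True), ("Q7A", True)]
_PATH_Q2 = [("Q1", False), ("Q2", True)]
_PATH_Q3 = [("Q1", False), ("Q2", False), ("Q3", True)]


@dataclass(frozen=True)
class LibraryEntry:
    """One curated structure with hand-verified hazard expectations."""

    name: str
    smiles: str
    cramer_class: str
    cramer_path: tuple
    mutagen_alerts: tuple = ()
    coc_flags: tuple = ()

    @property
    def hazard_label(self) -> str:
        return "mutagen" if self.mutagen_alerts else f"cramer_{self.cramer_class}"


#: curated structures: alkanols/esters/hydrocarbons (Class I), terpenoid and
#: other saturated O-heterocyclic ethers (Class II), heteroaromatics and
#: N-bearing aliphatics (Class III), nitroaromatics and other alert carriers
#: (mutagen), and two cohort-of-concern members (out-of-domain).
CURATED_LIBRARY: tuple[LibraryEntry, ...] = (
    # --- Class I ---
    LibraryEntry("ethanol", "CCO", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("1-butanol", "CCCCO", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("1-hexanol", "CCCCCCO", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("isoamyl alcohol", "CC(C)CCO", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("ethyl acetate", "CCOC(C)=O", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("ethyl butyrate", "CCCC(=O)OCC", "I", tuple(_PATH_OPEN_OK)),
    LibraryEntry("octane", "CCCCCCCC", "I", tuple(_PATH_Q5)),
    LibraryEntry("limonene", "CC1=CCC(CC1)C(=C)C", "I", tuple(_PATH_OPEN_OK)),
    # --- Class II ---
    LibraryEntry("rose oxide", "CC1CCOC(C1)C=C(C)C", "II", tuple(_PATH_OHET_OK)),
    LibraryEntry("tetrahydropyran", "C1CCOCC1", "II", tuple(_PATH_OHET_OK)),
    LibraryEntry("2-methyltetrahydrofuran", "CC1CCCO1", "II", tuple(_PATH_OHET_OK)),
    LibraryEntry("eucalyptol", "CC12CCC(CC1)C(C)(C)O2", "II", tuple(_PATH_OHET_OK)),
    LibraryEntry("linalool oxide", "C=CC1(C)CCC(C(C)(C)O)O1", "II", tuple(_PATH_OHET_OK)),
    # --- Class III ---
    LibraryEntry("pyridine", "c1ccncc1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("3-methylpyridine", "Cc1cccnc1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("furan", "c1ccoc1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("thiophene", "c1ccsc1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("pyrrole", "c1cc[nH]c1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("quinoline", "c1ccc2ncccc2c1", "III", tuple(_PATH_HETAROM)),
    LibraryEntry("triethylamine", "CCN(CC)CC", "III", tuple(_PATH_OPEN_BAD)),
    # --- mutagenicity alert carriers ---
    LibraryEntry("nitrobenzene", "O=[N+]([O-])c1ccccc1", "III",
                 tuple(_PATH_BENZENE_BAD), mutagen_alerts=("SA27",)),
    LibraryEntry("4-nitrotoluene", "Cc1ccc([N+](=O)[O-])cc1", "III",
                 tuple(_PATH_BENZENE_BAD), mutagen_alerts=("SA27",)),
    LibraryEntry("styrene oxide", "c1ccccc1C1CO1", "III",
                 tuple(_PATH_OHET_BAD), mutagen_alerts=("SA7",)),
    LibraryEntry("dichloromethane", "ClCCl", "III",
                 tuple(_PATH_Q3), mutagen_alerts=("SA8",)),
    LibraryEntry("acrolein", "C=CC=O", "I",
                 tuple(_PATH_OPEN_OK), mutagen_alerts=("SA10", "SA11")),
    # --- cohort of concern (out-of-domain) ---
    LibraryEntry("N-nitrosodimethylamine", "O=NN(C)C", "III",
                 tuple(_PATH_Q2), mutagen_alerts=("SA21",),
                 coc_flags=("COC_NITROSAMINE",)),
    LibraryEntry("parathion", "CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1", "III",
                 tuple(_PATH_Q3), mutagen_alerts=("SA27",),
                 coc_flags=("COC_OP",)),
)


@dataclass(frozen=True)
class PanelProfile:
    """Volatility range, hazard mix and (optional) margin strata of a panel."""

    vp_range_mmHg: tuple[float, float] = (1e-6, 1e2)
    hazard_mix: tuple[tuple[str, float], ...] = (
        ("cramer_I", 0.40),
        ("cramer_II", 0.20),
        ("cramer_III", 0.20),
        ("mutagen", 0.15),
        ("out_of_domain", 0.05),
    )
    #: target counts of safety margins in the strata (<1, 1–10, >10); the
    #: remainder after the first two goes to >10. Used when tox data is drawn.
    margin_strata: tuple[int, int] = (2, 3)


@dataclass
class FixtureExpectation:
    """Oracle-computed ground truth for one panel record."""

    record_id: str
    cramer_class: str
    cramer_path: list[tuple[str, bool]]
    mutagen_alerts: list[str]
    coc_flags: list[str]
    hazard_label: str
    ttc_ug_per_day: float
    neat_mass_ug: float
    max_conc_pct_ww: float
    capped: bool
    out_of_domain: bool
    #: only set when the panel carries tox data
    margin_water: float | None = None


@dataclass
class FixturePanel:
    """A reproducible synthetic panel plus its oracle expectations."""

    seed: int
    profile: PanelProfile
    records: list[ChemicalRecord]
    expected: list[FixtureExpectation]
    tox: dict[str, object] = field(default_factory=dict)  # id -> ToxRecord


def _oracle_neat_mass(vp_mmHg: float, mw: float) -> float:
    # straight-line ideal-gas arithmetic; intentionally not the headspace module
    return vp_mmHg * _MMHG_TO_ATM * mw * _VOLUME_L * 1e6 / (_R * _TEMP_K)


def _oracle_max_conc(ttc: float, exposure: float) -> tuple[float, bool]:
    if exposure <= ttc:
        return 100.0, True
    return ttc * 100.0 / exposure, False


def _oracle_water_mole_fraction(conc: float, mw: float) -> float:
    n_chem = conc / mw
    n_solv = (100.0 - conc) / _WATER_MW
    return n_chem / (n_chem + n_solv) if n_chem > 0 else 0.0


def generate_panel(
    n: int,
    seed: int,
    profile: PanelProfile | None = None,
    *,
    with_tox: bool = False,
) -> FixturePanel:
    """Generate a deterministic panel of *n* chemicals.

    Vapor pressures are drawn log-uniformly over the profile's range;
    structures are drawn from the curated library according to the hazard
    mix; molecular weights are the structures' true values. With
    ``with_tox=True`` each record also gets a NOAEC chosen so the water
    safety margins hit the profile's strata counts exactly.
    """
    if n < 1:
        raise InputError(f"panel size must be >= 1, got {n}")
    profile = profile or PanelProfile()
    lo, hi = profile.vp_range_mmHg
    if lo < 0 or hi < lo:
        raise InputError(f"bad vapor-pressure range {profile.vp_range_mmHg}")
    rng = np.random.default_rng(seed)

    by_label: dict[str, list[LibraryEntry]] = {}
    for e in CURATED_LIBRARY:
        label = "out_of_domain" if e.coc_flags else e.hazard_label
        by_label.setdefault(label, []).append(e)
    labels = [lbl for lbl, _ in profile.hazard_mix]
    weights = np.array([w for _, w in profile.hazard_mix], dtype=float)
    weights /= weights.sum()

    records: list[ChemicalRecord] = []
    expected: list[FixtureExpectation] = []
    for i in range(n):
        label = labels[int(rng.choice(len(labels), p=weights))]
        pool = by_label[label]
        entry = pool[int(rng.integers(len(pool)))]
        if hi > lo > 0:
            vp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            vp = float(lo)
        rec = ChemicalRecord(
            id=f"FIX{i:03d}", name=entry.name, smiles=entry.smiles, vp_mmHg=vp
        )
        records.append(rec)

        ttc = _TTC[entry.hazard_label]
        mass = _oracle_neat_mass(vp, rec.mw)
        conc, capped = _oracle_max_conc(ttc, mass)
        expected.append(
            FixtureExpectation(
                record_id=rec.id,
                cramer_class=entry.cramer_class,
                cramer_path=list(entry.cramer_path),
                mutagen_alerts=list(entry.mutagen_alerts),
                coc_flags=list(entry.coc_flags),
                hazard_label=entry.hazard_label,
                ttc_ug_per_day=ttc,
                neat_mass_ug=mass,
                max_conc_pct_ww=conc,
                capped=capped,
                out_of_domain=bool(entry.coc_flags),
            )
        )

    panel = FixturePanel(seed=seed, profile=profile, records=records, expected=expected)
    if with_tox:
        _attach_tox(panel, rng)
    return panel


def _attach_tox(panel: FixturePanel, rng: np.random.Generator) -> None:
    """Draw NOAECs so water margins land in the requested strata exactly."""
    # container type only; the margin arithmetic below is the oracle's own
    from .validation import ToxRecord

    n = len(panel.records)
    n_low, n_mid = panel.profile.margin_strata
    if n_low + n_mid > n:
        raise InputError(
            f"margin strata {panel.profile.margin_strata} exceed panel size {n}"
        )
    target_margins = (
        [float(rng.uniform(0.2, 0.8)) for _ in range(n_low)]
        + [float(rng.uniform(2.0, 8.0)) for _ in range(n_mid)]
        + [float(10 ** rng.uniform(1.5, 5.0)) for _ in range(n - n_low - n_mid)]
    )
    for rec, exp, margin in zip(panel.records, panel.expected, target_margins):
        if exp.capped:
            adj_mass = exp.neat_mass_ug
        else:
            x = _oracle_water_mole_fraction(exp.max_conc_pct_ww, rec.mw)
            adj_mass = _oracle_neat_mass(x * rec.vp_mmHg, rec.mw)
        noael = margin * adj_mass                      # μg/day
        noaec = noael / (0.2 * 360.0)                  # mg/m³ at default factors
        panel.tox[rec.id] = ToxRecord(chemical_id=rec.id, noaec_mg_m3=noaec)
        exp.margin_water = margin
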