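"""Structure-based hazard classification and TTC assignment.

The screening model stacks three structure-based predictors — SMARTS alerts
for bacterial (Ames) mutagenicity, the Cramer decision tree for systemic
toxicity, and an exclusion screen for cohort-of-concern classes — and takes
the most severe prediction. Each hazard label maps to a Threshold of
Toxicological Concern (TTC, μg/day): mutagens get the acute (<30 day)
less-than-lifetime value of 12 μg/day; Cramer classes III/II/I get the Kroes
values 90/540/1800 μg/day.

Rulebooks are versioned CSV files shipped with the package; their checksums
are logged at load time and recorded in every result's audit trail.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources

from rdkit import Chem

from . import cramer as _cramer
from .chem import parse_smiles
from .errors import ConfigurationError, LoadError

logger = logging.getLogger(__name__)

#: hazard labels from most to least severe
HAZARD_PRECEDENCE = ("mutagen", "cramer_III", "cramer_II", "cramer_I")

#: default TTC table (μg/day) keyed by hazard label
DEFAULT_TTC: dict[str, float] = {
    "mutagen": 12.0,
    "cramer_III": 90.0,
    "cramer_II": 540.0,
    "cramer_I": 1800.0,
}


@dataclass(frozen=True)
class StructuralAlert:
    """One SMARTS-encoded structural alert."""

    alert_id: str
    description: str
    smarts: str
    category: str  # "mutagenicity" or "cohort_of_concern"

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise LoadError(f"alert {self.alert_id}: SMARTS does not parse: {self.smarts!r}")
        return patt


@dataclass
class Rulebook:
    """A versioned collection of structural alerts loaded from CSV."""

    name: str
    version: str
    checksum: str
    alerts: list[StructuralAlert]
    _patterns: list[tuple[str, Chem.Mol]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for alert in self.alerts:
            if alert.alert_id in seen:
                raise LoadError(f"rulebook {self.name}: duplicate alert id {alert.alert_id}")
            seen.add(alert.alert_id)
            self._patterns.append((alert.alert_id, alert.pattern()))

    def match(self, mol: Chem.Mol) -> list[str]:
        """Return ids of all alerts whose SMARTS match *mol*."""
        return [aid for aid, patt in self._patterns if mol.HasSubstructMatch(patt)]

    @property
    def tag(self) -> str:
        return f"{self.name} v{self.version} sha256:{self.checksum[:8]}"


def _load_rulebook(filename: str, category: str) -> Rulebook:
    ref = resources.files("odorsafe.rulebooks").joinpath(filename)
    raw = ref.read_bytes()
    checksum = hashlib.sha256(raw).hexdigest()
    lines = raw.decode("utf-8").splitlines()
    name = version = None
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            meta = line.lstrip("# ").strip()
            if meta.startswith("rulebook:"):
                name = meta.split(":", 1)[1].strip()
            elif meta.startswith("version:"):
                version = meta.split(":", 1)[1].strip()
        else:
            body.append(line)
    if name is None or version is None:
        raise LoadError(f"{filename}: missing '# rulebook:'/'# version:' header")
    alerts = [
        StructuralAlert(row["alert_id"], row["description"], row["smarts"], category)
        for row in csv.DictReader(body)
        if row.get("alert_id")
    ]
    book = Rulebook(name=name, version=version, checksum=checksum, alerts=alerts)
    logger.info("loaded rulebook %s (%d alerts)", book.tag, len(alerts))
    return book


_MUTAGENICITY: Rulebook | None = None
_COHORT: Rulebook | None = None


def mutagenicity_rulebook() -> Rulebook:
    global _MUTAGENICITY
    if _MUTAGENICITY is None:
        _MUTAGENICITY = _load_rulebook("mutagenicity_v1.csv", "mutagenicity")
    return _MUTAGENICITY


def cohort_of_concern_rulebook() -> Rulebook:
    global _COHORT
    if _COHORT is None:
        _COHORT = _load_rulebook("cohort_of_concern_v1.csv", "cohort_of_concern")
    return _COHORT


def classify_mutagenicity(smiles: str, rulebook: Rulebook | None = None) -> list[str]:
    """All matching mutagenicity alert ids for *smiles* (empty list = no alerts)."""
    book = rulebook or mutagenicity_rulebook()
    return book.match(parse_smiles(smiles))


def check_cohort_of_concern(smiles: str, rulebook: Rulebook | None = None) -> list[str]:
    """Matching cohort-of-concern exclusion-class alert ids for *smiles*.

    Any match means TTC-based screening is invalid for the chemical; callers
    must surface the out-of-domain marker rather than trust the numbers.
    """
    book = rulebook or cohort_of_concern_rulebook()
    return book.match(parse_smiles(smiles))


def classify_cramer(smiles: str):
    """Cramer class ("I"/"II"/"III") and audit path for *smiles*.

    Thin re-export of :func:`odorsafe.cramer.classify_cramer`.
    """
    return _cramer.classify_cramer(smiles)


def assign_hazard(mutagen_alerts: list[str], cramer_class: str) -> str:
    """Most severe hazard label: mutagen > cramer_III > cramer_II > cramer_I.

    A non-empty alert list wins regardless of the Cramer class.
    """
    if cramer_class not in ("I", "II", "III"):
        raise ConfigurationError(f"invalid Cramer class {cramer_class!r}")
    if mutagen_alerts:
        return "mutagen"
    return f"cramer_{cramer_class}"


def assign_ttc(hazard_label: str, ttc_table: dict[str, float] | None = None) -> float:
    """TTC in μg/day for a hazard label (defaults: 12 / 90 / 540 / 1800)."""
    table = DEFAULT_TTC if ttc_table is None else ttc_table
    try:
        return float(table[hazard_label])
    except KeyError:
        raise ConfigurationError(
            f"no TTC configured for hazard label {hazard_label!r}"
        ) from None


@dataclass
class HazardResult:
    """Full hazard characterization of one chemical."""

    mutagen_alerts: list[str]
    cramer_class: str
    cramer_path: list[tuple[str, bool]]
    hazard_label: str
    coc_flags: list[str]
    ttc_ug_per_day: float
    rulebook_versions: dict[str, str]

    @property
    def out_of_domain(self) -> bool:
        """True when the chemical belongs to a cohort-of-concern class."""
        return bool(self.coc_flags)


def classify(smiles: str, ttc_table: dict[str, float] | None = None) -> HazardResult:
    """Run the full hazard stack on one SMILES and assign its TTC."""
    alerts = classify_mutagenicity(smiles)
    cls, path = _cramer.classify_cramer(smiles)
    coc = check_cohort_of_concern(smiles)
    label = assign_hazard(alerts, cls)
    return HazardResult(
        mutagen_alerts=alerts,
        cramer_class=cls,
        cramer_path=path,
        hazard_label=label,
        coc_flags=coc,
        ttc_ug_per_day=assign_ttc(label, ttc_table),
        rulebook_versions={
            "mutagenicity": mutagenicity_rulebook().tag,
            "cohort_of_concern": cohort_of_concern_rulebook().tag,
            "cramer": _cramer.cramer_rulebook().tag,
        },
    )
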