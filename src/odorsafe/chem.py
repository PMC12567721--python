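"""Chemical records and SMILES handling.

Molecules are canonicalized exactly once on ingest; every downstream SMARTS
match runs against the canonical form, so two encodings of the same molecule
always yield identical results. Multi-fragment SMILES (salts, mixtures) are
rejected: the screening model addresses a single volatile species per record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .errors import InputError, StructureError

RDLogger.DisableLog("rdApp.error")

logger = logging.getLogger(__name__)

#: relative tolerance for supplied-vs-computed molecular weight cross-checks
MW_RTOL = 0.005


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Raises
    ------
    StructureError
        If the string does not parse, or encodes more than one fragment.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise StructureError(str(smiles), "is empty")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise StructureError(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise StructureError(
            smiles, "encodes multiple fragments (salts/mixtures are not supported)"
        )
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES for *smiles* (raises StructureError on bad input)."""
    return Chem.MolToSmiles(parse_smiles(smiles))


def molecular_weight(smiles: str) -> float:
    """Average molecular weight (g/mol) computed from the structure."""
    return float(Descriptors.MolWt(parse_smiles(smiles)))


@dataclass
class ChemicalRecord:
    """One volatile chemical entering the screening pipeline.

    Parameters
    ----------
    id : str
        Caller-chosen identifier, carried through all outputs.
    name : str
        Human-readable name.
    smiles : str
        Structure; canonicalized on construction.
    vp_mmHg : float
        Vapor pressure at 25 degC in mmHg (from an external predictor such as
        MPBPWIN, or an experimental value).
    mw : float, optional
        Molar mass in g/mol. Computed from the structure when omitted.
    cas : str, optional
        CAS registry number, informational only.
    vp_source : {"predicted", "experimental"}
        Provenance of the vapor pressure.
    """

    id: str
    name: str
    smiles: str
    vp_mmHg: float
    mw: float | None = None
    cas: str | None = None
    vp_source: str = "predicted"
    #: "supplied" or "computed"; set automatically
    mw_source: str = field(default="supplied")
    #: True when a supplied MW disagrees with the structure by > 0.5 %
    mw_mismatch: bool = field(default=False)

    def __post_init__(self) -> None:
        self.smiles = canonical_smiles(self.smiles)
        if self.vp_source not in ("predicted", "experimental"):
            raise InputError(f"vp_source must be predicted/experimental, got {self.vp_source!r}")
        self.vp_mmHg = float(self.vp_mmHg)
        if self.vp_mmHg < 0:
            raise InputError(f"vapor pressure must be >= 0 mmHg, got {self.vp_mmHg}")
        computed = molecular_weight(self.smiles)
        if self.mw is None:
            self.mw = computed
            self.mw_source = "computed"
        else:
            self.mw = float(self.mw)
            if self.mw <= 0:
                raise InputError(f"molecular weight must be > 0, got {self.mw}")
            if abs(self.mw - computed) > MW_RTOL * computed:
                self.mw_mismatch = True
                logger.warning(
                    "record %s: supplied MW %.2f deviates >%.1f%% from computed %.2f",
                    self.id, self.mw, 100 * MW_RTOL, computed,
                )

    @property
    def mol(self) -> Chem.Mol:
        return parse_smiles(self.smiles)
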