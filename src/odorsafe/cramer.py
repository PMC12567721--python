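"""Cramer decision-tree classification for systemic-toxicity concern.

The tree assigns one of three structural classes (I low, II intermediate,
III high concern) by answering a sequence of yes/no structural questions.
The question graph is data — a versioned CSV shipped with the package
(``rulebooks/cramer_v1.csv``) whose rows name predicates registered here —
so the traversal is fully auditable: :func:`classify_cramer` returns the
exact (question id, answer) path alongside the class.

This is a condensed encoding of the published Cramer question sequence,
tuned to the chemical space of volatile odorants (hydrocarbons, alcohols,
esters, ethers, carbonyls, heteroaromatics); divergences from Toxtree's
revised tree are documented in the methods note, and external per-chemical
class overrides are accepted at the workflow level for users who run
Toxtree directly.

Molecules containing elements outside the tree's coverage (metals,
metalloids) raise :class:`~odorsafe.errors.OutOfDomainError` instead of
being silently assigned Class III.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass
from importlib import resources

from rdkit import Chem

from .chem import canonical_smiles, parse_smiles
from .errors import LoadError, OutOfDomainError

logger = logging.getLogger(__name__)

#: elements the decision tree can reason about
COVERED_ELEMENTS = frozenset([1, 6, 7, 8, 9, 15, 16, 17, 35, 53])

TERMINALS = {"CLASS_I": "I", "CLASS_II": "II", "CLASS_III": "III"}


def _smarts(s: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(s)
    assert patt is not None, s
    return patt


# --- structural vocabulary used by the predicates --------------------------

_ENHANCED_TOXICITY = [
    _smarts(s)
    for s in (
        "[NX3H1;!$([NX3]C=[O,S,N])]([CX4])[CX4]",  # aliphatic secondary amine
        "[CX2]#[NX1]",                             # cyano
        "[NX3][NX2]=[OX1]",                        # N-nitroso
        "[NX2]=[NX2]",                             # diazo / azo (covers triazeno)
        "[NX4+]",                                  # quaternary nitrogen
    )
]

# functional groups recognized for the "innocuous substituents" questions;
# names are informational (they appear in audit output)
_FUNCTIONAL_GROUPS = {
    "alcohol": _smarts("[OX2H][#6;!$([CX3]=[OX1])]"),
    "ether": _smarts("[OX2;!$([OX2][CX3]=[OX1]);!$([OX2][OX2])]([#6])[#6]"),
    "aldehyde": _smarts("[CX3H1]=[OX1]"),
    "ketone": _smarts("[#6][CX3](=[OX1])[#6]"),
    "carboxylic_acid": _smarts("[CX3](=[OX1])[OX2H1]"),
    "ester": _smarts("[CX3](=[OX1])[OX2][#6]"),
    "alkene": _smarts("[CX3]=[CX3]"),
    "alkyne": _smarts("[CX2]#[CX2]"),
    "thiol": _smarts("[SX2H]"),
    "sulfide": _smarts("[SX2]([#6])[#6]"),
}

_PEROXIDE = _smarts("[OX2][OX2]")
_LACTONE = _smarts("[#6;R](=[OX1])[#8;R]")
_UNSAT_LACTONE = _smarts(
    "[$([#8;R][#6;R](=[OX1])[#6]=[#6]),$([#8;R][#6;R](=[OX1])[#6;a]),"
    "$([#8;R][#6;R](=[OX1])[#6;R]=[#6;R])]"
)

#: canonical SMILES of normal body constituents / harmless metabolites
_BODY_CONSTITUENTS = {
    canonical_smiles(s)
    for s in ("O", "O=C=O", "OCC(O)CO", "CC(O)C(=O)O", "NC(N)=O", "OC(=O)CC(=O)O")
}

#: canonical SMILES of common carbohydrates accepted at the hydrocarbon/sugar gate
_COMMON_SUGARS = {
    canonical_smiles(s)
    for s in (
        "OCC1OC(O)C(O)C(O)C1O",                     # hexopyranose (glucose-like)
        "OCC1OC(O)(CO)C(O)C1O",                     # ketohexose (fructose-like)
    )
}


def _elements_within(mol: Chem.Mol, allowed: set[int]) -> bool:
    return all(a.GetAtomicNum() in allowed for a in mol.GetAtoms())


def _sulfur_divalent(mol: Chem.Mol) -> bool:
    return all(
        a.GetTotalValence() == 2 and a.GetFormalCharge() == 0
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 16
    )


def _innocuous_cho_skeleton(mol: Chem.Mol, allow_sulfur: bool = True) -> bool:
    """True when the molecule is built only from C/H/O (optionally divalent S)
    and contains no structural features outside the recognized innocuous set."""
    allowed = {1, 6, 8} | ({16} if allow_sulfur else set())
    if not _elements_within(mol, allowed):
        return False
    if not _sulfur_divalent(mol):
        return False
    if mol.HasSubstructMatch(_PEROXIDE):
        return False
    return True


def detected_groups(mol: Chem.Mol) -> list[str]:
    """Names of recognized functional groups present in *mol* (audit aid)."""
    return [name for name, patt in _FUNCTIONAL_GROUPS.items() if mol.HasSubstructMatch(patt)]


# --- predicate registry ----------------------------------------------------

def _p_body_constituent(mol: Chem.Mol) -> bool:
    return Chem.MolToSmiles(mol) in _BODY_CONSTITUENTS


def _p_enhanced_toxicity_groups(mol: Chem.Mol) -> bool:
    return any(mol.HasSubstructMatch(p) for p in _ENHANCED_TOXICITY)


def _p_unusual_elements(mol: Chem.Mol) -> bool:
    if not _elements_within(mol, {1, 6, 7, 8, 16}):
        return True
    return not _sulfur_divalent(mol)


def _p_simple_hydrocarbon_or_sugar(mol: Chem.Mol) -> bool:
    if _elements_within(mol, {1, 6}) and mol.GetRingInfo().NumRings() == 0:
        return True
    return Chem.MolToSmiles(mol) in _COMMON_SUGARS


def _p_heterocyclic(mol: Chem.Mol) -> bool:
    return any(a.IsInRing() and a.GetAtomicNum() != 6 for a in mol.GetAtoms())


def _p_heteroaromatic(mol: Chem.Mol) -> bool:
    return any(a.GetIsAromatic() and a.GetAtomicNum() != 6 for a in mol.GetAtoms())


def _p_lactone(mol: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(_LACTONE)


def _p_unsaturated_lactone(mol: Chem.Mol) -> bool:
    return mol.HasSubstructMatch(_UNSAT_LACTONE)


def _p_innocuous_o_heterocycle(mol: Chem.Mol) -> bool:
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        return False
    if any(a.IsInRing() and a.GetAtomicNum() not in (6, 8) for a in mol.GetAtoms()):
        return False
    return _innocuous_cho_skeleton(mol, allow_sulfur=False)


def _p_has_aromatic_ring(mol: Chem.Mol) -> bool:
    return any(a.GetIsAromatic() for a in mol.GetAtoms())


def _p_innocuous_benzene(mol: Chem.Mol) -> bool:
    ri = mol.GetRingInfo()
    aromatic_rings = [
        ring for ring in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    ]
    for ring in aromatic_rings:
        if len(ring) != 6:
            return False
        if any(mol.GetAtomWithIdx(i).GetAtomicNum() != 6 for i in ring):
            return False
    # fused aromatic systems (naphthalenes and larger) are not "mononuclear"
    for i, r1 in enumerate(aromatic_rings):
        for r2 in aromatic_rings[i + 1:]:
            if len(set(r1) & set(r2)) >= 2:
                return False
    return _innocuous_cho_skeleton(mol)


def _p_innocuous_aliphatic_groups(mol: Chem.Mol) -> bool:
    return _innocuous_cho_skeleton(mol)


PREDICATES = {
    "body_constituent": _p_body_constituent,
    "enhanced_toxicity_groups": _p_enhanced_toxicity_groups,
    "unusual_elements": _p_unusual_elements,
    "simple_hydrocarbon_or_sugar": _p_simple_hydrocarbon_or_sugar,
    "heterocyclic": _p_heterocyclic,
    "heteroaromatic": _p_heteroaromatic,
    "lactone": _p_lactone,
    "unsaturated_lactone": _p_unsaturated_lactone,
    "innocuous_o_heterocycle": _p_innocuous_o_heterocycle,
    "has_aromatic_ring": _p_has_aromatic_ring,
    "innocuous_benzene": _p_innocuous_benzene,
    "innocuous_aliphatic_groups": _p_innocuous_aliphatic_groups,
}


# --- question table --------------------------------------------------------

@dataclass(frozen=True)
class Question:
    question_id: str
    text: str
    predicate: str
    if_yes: str
    if_no: str


@dataclass
class CramerRulebook:
    name: str
    version: str
    checksum: str
    questions: dict[str, Question]
    root: str

    @property
    def tag(self) -> str:
        return f"{self.name} v{self.version} sha256:{self.checksum[:8]}"


_RULEBOOK: CramerRulebook | None = None


def cramer_rulebook() -> CramerRulebook:
    global _RULEBOOK
    if _RULEBOOK is None:
        ref = resources.files("odorsafe.rulebooks").joinpath("cramer_v1.csv")
        raw = ref.read_bytes()
        checksum = hashlib.sha256(raw).hexdigest()
        name = version = None
        body: list[str] = []
        for line in raw.decode("utf-8").splitlines():
            if line.startswith("#"):
                meta = line.lstrip("# ").strip()
                if meta.startswith("rulebook:"):
                    name = meta.split(":", 1)[1].strip()
                elif meta.startswith("version:"):
                    version = meta.split(":", 1)[1].strip()
            else:
                body.append(line)
        questions: dict[str, Question] = {}
        root = None
        for row in csv.DictReader(body):
            if not row.get("question_id"):
                continue
            q = Question(row["question_id"], row["text"], row["predicate"],
                         row["if_yes"], row["if_no"])
            if q.predicate not in PREDICATES:
                raise LoadError(f"cramer question {q.question_id}: unknown predicate {q.predicate!r}")
            if q.question_id in questions:
                raise LoadError(f"cramer question {q.question_id}: duplicate id")
            questions[q.question_id] = q
            if root is None:
                root = q.question_id
        for q in questions.values():
            for succ in (q.if_yes, q.if_no):
                if succ not in questions and succ not in TERMINALS:
                    raise LoadError(f"cramer question {q.question_id}: unknown successor {succ!r}")
        if name is None or version is None or root is None:
            raise LoadError("cramer rulebook: missing header or empty table")
        _RULEBOOK = CramerRulebook(name, version, checksum, questions, root)
        logger.info("loaded rulebook %s (%d questions)", _RULEBOOK.tag, len(questions))
    return _RULEBOOK


def classify_cramer(smiles: str) -> tuple[str, list[tuple[str, bool]]]:
    """Classify *smiles* into Cramer class "I", "II" or "III".

    Returns
    -------
    (cramer_class, path)
        ``path`` is the ordered list of (question id, answer) pairs walked by
        the traversal, for audit.

    Raises
    ------
    StructureError
        If the SMILES does not parse to a single-fragment molecule.
    OutOfDomainError
        If the molecule contains elements outside the tree's coverage.
    """
    mol = parse_smiles(smiles)
    bad = sorted({a.GetSymbol() for a in mol.GetAtoms()
                  if a.GetAtomicNum() not in COVERED_ELEMENTS})
    if bad:
        raise OutOfDomainError(smiles, f"elements outside tree coverage: {', '.join(bad)}")
    book = cramer_rulebook()
    node = book.root
    path: list[tuple[str, bool]] = []
    while node not in TERMINALS:
        q = book.questions[node]
        answer = bool(PREDICATES[q.predicate](mol))
        path.append((q.question_id, answer))
        node = q.if_yes if answer else q.if_no
        if len(path) > len(book.questions):  # pragma: no cover - malformed table guard
            raise LoadError("cramer rulebook: traversal did not terminate")
    return TERMINALS[node], path
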