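"""Dataset curation for enoyl-ACP reductase (ENR) inhibitor records.

Raw records (SMILES + IC50 + enzyme label) are standardized, qualitative
inactives are imputed at IC50 = 100 uM, duplicates are collapsed keeping the
most potent measurement, IC50 is converted to pIC50, and each molecule is
classified active/inactive at a pIC50 threshold of 5.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

ENZYMES = ("InhA", "FabI", "FabK", "FabV")

#: pIC50 at or above which a compound is called active.
ACTIVITY_THRESHOLD = 5.5

#: Molar IC50 assigned to qualitative inactives (enzyme activity > 80 % or
#: inhibition < 20 % in the source assay, or IC50 simply not reported).
IMPUTED_INACTIVE_IC50_M = 1.0e-4


class CurationError(ValueError):
    """Raised for records that cannot be curated."""


class SmilesParseError(CurationError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass
class MoleculeRecord:
    """One curated compound: structure, activity, enzyme label."""

    id: str
    smiles_raw: str
    smiles: str = ""
    enzyme: str = ""
    ic50: Optional[float] = None  # molar
    pic50: Optional[float] = None
    activity_class: str = ""
    qualitative_inactive: bool = False
    source: str = ""
    extras: dict = field(default_factory=dict)


_largest_fragment = rdMolStandardize.LargestFragmentChooser()
_uncharger = rdMolStandardize.Uncharger()


def standardize_structure(smiles_raw: str) -> str:
    """Canonical SMILES of the largest covalent fragment.

    Salts and co-crystallized solvents are stripped by keeping the largest
    fragment, charges are neutralized where possible, and explicit
    stereochemistry is preserved.  Idempotent.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise SmilesParseError(smiles_raw)
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise SmilesParseError(smiles_raw)
    mol = _largest_fragment.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise CurationError(f"empty structure after fragment stripping: {smiles_raw!r}")
    mol = _uncharger.uncharge(mol)
    return Chem.MolToSmiles(mol)


def ic50_to_pic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 / 1 M)."""
    if not (ic50 > 0) or not math.isfinite(ic50):
        raise CurationError(f"IC50 must be a positive finite molar value, got {ic50}")
    return -math.log10(ic50)


def classify_activity(pic50: float, threshold: float = ACTIVITY_THRESHOLD) -> str:
    """'active' iff pIC50 >= threshold (default 5.5), else 'inactive'."""
    if not math.isfinite(pic50):
        raise CurationError(f"pIC50 must be finite, got {pic50}")
    return "active" if pic50 >= threshold else "inactive"


def impute_inactive(record: MoleculeRecord) -> MoleculeRecord:
    """Set IC50 = 100 uM for qualitative inactives / missing IC50.

    A record that already carries a quantitative IC50 and is not flagged
    qualitative-inactive is returned unchanged (no-op).
    """
    if record.ic50 is not None and not record.qualitative_inactive:
        return record
    return replace(record, ic50=IMPUTED_INACTIVE_IC50_M, qualitative_inactive=True)


def deduplicate(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """Collapse duplicates per (canonical SMILES, enzyme), keeping max pIC50.

    Ties are broken by the lexicographically smallest id so the survivor is
    deterministic regardless of input order.
    """
    best: dict[tuple[str, str], MoleculeRecord] = {}
    for rec in records:
        key = (rec.smiles, rec.enzyme)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
        elif (rec.pic50, _neg_id(rec)) > (cur.pic50, _neg_id(cur)):
            best[key] = rec
    return sorted(best.values(), key=lambda r: r.id)


def _neg_id(rec: MoleculeRecord) -> tuple:
    # Higher tuple wins in deduplicate(); invert id ordering so that the
    # *smallest* id wins on pIC50 ties.
    return tuple(-ord(c) for c in rec.id)


@dataclass
class CurationLog:
    n_input: int = 0
    n_output: int = 0
    dropped: dict = field(default_factory=dict)
    n_imputed: int = 0
    n_duplicates_removed: int = 0

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


def curate(
    records: Iterable[MoleculeRecord],
    threshold: float = ACTIVITY_THRESHOLD,
) -> tuple[list[MoleculeRecord], CurationLog]:
    """Full curation pipeline.

    standardize -> drop unusable -> impute qualitative inactives ->
    pIC50 conversion -> deduplicate (max potency survives) -> classify.
    Curating an already-curated list is a no-op (idempotent).
    """
    log = CurationLog()
    staged: list[MoleculeRecord] = []
    for rec in records:
        log.n_input += 1
        if rec.enzyme not in ENZYMES:
            log.drop("missing_or_unknown_enzyme")
            continue
        try:
            smiles = standardize_structure(rec.smiles_raw)
        except CurationError:
            log.drop("unparsable_smiles")
            continue
        rec = replace(rec, smiles=smiles)
        if rec.ic50 is None or rec.qualitative_inactive:
            if rec.ic50 is None or not rec.qualitative_inactive:
                log.n_imputed += 1
            rec = impute_inactive(rec)
        rec = replace(rec, pic50=ic50_to_pic50(rec.ic50))
        rec = replace(rec, activity_class=classify_activity(rec.pic50, threshold))
        staged.append(rec)
    out = deduplicate(staged)
    log.n_duplicates_removed = len(staged) - len(out)
    log.n_output = len(out)
    return out, log


# ---------------------------------------------------------------------------
# I/O

CSV_COLUMNS = ["id", "smiles", "enzyme", "ic50_nM", "qualitative_inactive", "source"]


def read_csv(path: str | Path) -> list[MoleculeRecord]:
    """Read the package CSV dialect (`id,smiles,enzyme,ic50_nM,...`)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        ic50_nm = getattr(row, "ic50_nM", None)
        ic50 = None if ic50_nm is None or pd.isna(ic50_nm) else float(ic50_nm) * 1e-9
        records.append(
            MoleculeRecord(
                id=str(row.id),
                smiles_raw=str(row.smiles),
                enzyme=str(row.enzyme),
                ic50=ic50,
                qualitative_inactive=bool(getattr(row, "qualitative_inactive", False)),
                source=str(getattr(row, "source", "")),
            )
        )
    return records


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """Read an SDF whose SD tags mirror the CSV columns."""
    records = []
    for mol in Chem.SDMolSupplier(str(path)):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        ic50_nm = props.get("ic50_nM")
        records.append(
            MoleculeRecord(
                id=str(props.get("id", mol.GetProp("_Name") if mol.HasProp("_Name") else "")),
                smiles_raw=Chem.MolToSmiles(mol),
                enzyme=str(props.get("enzyme", "")),
                ic50=None if ic50_nm in (None, "") else float(ic50_nm) * 1e-9,
                qualitative_inactive=str(props.get("qualitative_inactive", "False")).lower()
                in ("1", "true"),
                source=str(props.get("source", "")),
            )
        )
    return records


def curated_frame(records: Iterable[MoleculeRecord]) -> pd.DataFrame:
    """Curated records as a DataFrame (one row per molecule)."""
    records = list(records)
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "enzyme": [r.enzyme for r in records],
            "ic50_M": [r.ic50 for r in records],
            "pic50": [r.pic50 for r in records],
            "activity_class": [r.activity_class for r in records],
            "source": [r.source for r in records],
        }
    )
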