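"""Physicochemical descriptor panel, Lipinski rule, and PAINS/Brenk filters.

The panel is a fixed set of 39 named descriptors.  Most come from RDKit;
three that RDKit does not expose directly are implemented here from their
published definitions:

* ``apol`` — sum of atomic polarizabilities over all atoms including
  hydrogens (values in 10^-24 cm^3 from standard tables).
* ``fragCpx`` — Nilakantan fragment complexity ``|B^2 - A^2 + A| + H/100``
  with B bonds, A heavy atoms, H heteroatoms.
* ``LogS`` — ESOL-style aqueous solubility estimate (log mol/L) from logP,
  molecular weight, rotatable-bond and aromatic-proportion terms.

PAINS and Brenk substructure screens use RDKit's curated filter catalogs;
hit names are the catalog entry descriptions.
"""

from __future__ import annotations

import math
from typing import Optional

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

__all__ = [
    "PANEL",
    "compute_descriptors",
    "lipinski_violations",
    "pains_hits",
    "brenk_hits",
    "filter_report",
]


class DescriptorError(ValueError):
    pass


# Atomic polarizabilities (10^-24 cm^3); CRC-style static dipole values.
_POLARIZABILITY = {
    1: 0.666793, 5: 3.03, 6: 1.76, 7: 1.10, 8: 0.802, 9: 0.557,
    14: 5.38, 15: 3.63, 16: 2.90, 17: 2.18, 34: 3.77, 35: 3.05, 53: 5.35,
}


def _apol(mol: Chem.Mol) -> float:
    molh = Chem.AddHs(mol)
    total = 0.0
    for atom in molh.GetAtoms():
        alpha = _POLARIZABILITY.get(atom.GetAtomicNum())
        if alpha is None:
            raise DescriptorError(
                f"no polarizability tabulated for element Z={atom.GetAtomicNum()}"
            )
        total += alpha
    return total


def _frag_cpx(mol: Chem.Mol) -> float:
    a = mol.GetNumHeavyAtoms()
    b = mol.GetNumBonds()
    h = sum(1 for at in mol.GetAtoms() if at.GetAtomicNum() not in (1, 6))
    return abs(b * b - a * a + a) + h / 100.0


def _esol_logs(mol: Chem.Mol) -> float:
    # Delaney ESOL: 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy) if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _rotb_frac(mol: Chem.Mol) -> float:
    nb = mol.GetNumBonds()
    return rdMolDescriptors.CalcNumRotatableBonds(mol) / nb if nb else 0.0


def _num_stereocenters(mol: Chem.Mol) -> int:
    return rdMolDescriptors.CalcNumAtomStereoCenters(mol)


#: name -> callable; the fixed 39-descriptor panel.
PANEL = {
    "SlogP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "AMW": Descriptors.MolWt,
    "NumRotatableBonds": rdMolDescriptors.CalcNumRotatableBonds,
    "NumHBD": rdMolDescriptors.CalcNumHBD,
    "NumHBA": rdMolDescriptors.CalcNumHBA,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "NumStereocenters": _num_stereocenters,
    "FractionCSP3": rdMolDescriptors.CalcFractionCSP3,
    "apol": _apol,
    "RotBFrac": _rotb_frac,
    "BertzCT": GraphDescriptors.BertzCT,
    "fragCpx": _frag_cpx,
    "LogS": _esol_logs,
    "NumRings": rdMolDescriptors.CalcNumRings,
    "NumHeavyAtoms": lambda m: m.GetNumHeavyAtoms(),
    "NumHeteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "NumAliphaticRings": rdMolDescriptors.CalcNumAliphaticRings,
    "NumSaturatedRings": rdMolDescriptors.CalcNumSaturatedRings,
    "NumAromaticHeterocycles": rdMolDescriptors.CalcNumAromaticHeterocycles,
    "NumAromaticCarbocycles": rdMolDescriptors.CalcNumAromaticCarbocycles,
    "NumAmideBonds": rdMolDescriptors.CalcNumAmideBonds,
    "MolMR": Crippen.MolMR,
    "LabuteASA": rdMolDescriptors.CalcLabuteASA,
    "BalabanJ": GraphDescriptors.BalabanJ,
    "Chi0v": rdMolDescriptors.CalcChi0v,
    "Chi1v": rdMolDescriptors.CalcChi1v,
    "Kappa1": rdMolDescriptors.CalcKappa1,
    "Kappa2": rdMolDescriptors.CalcKappa2,
    "Kappa3": rdMolDescriptors.CalcKappa3,
    "HallKierAlpha": rdMolDescriptors.CalcHallKierAlpha,
    "NumSpiroAtoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "NumBridgeheadAtoms": rdMolDescriptors.CalcNumBridgeheadAtoms,
    "QED": Descriptors.qed,
    "NumSaturatedCarbocycles": rdMolDescriptors.CalcNumSaturatedCarbocycles,
    "NumAliphaticHeterocycles": rdMolDescriptors.CalcNumAliphaticHeterocycles,
    "NHOHCount": Lipinski.NHOHCount,
    "NOCount": Lipinski.NOCount,
    "FormalCharge": lambda m: Chem.GetFormalCharge(m),
}

assert len(PANEL) == 39


def _as_mol(mol_or_smiles) -> Chem.Mol:
    # reparse from canonical SMILES: descriptors are functions of the
    # canonical structure, so atom ordering must not leak into float sums
    if isinstance(mol_or_smiles, Chem.Mol):
        return Chem.MolFromSmiles(Chem.MolToSmiles(mol_or_smiles))
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise DescriptorError(f"unparsable SMILES: {mol_or_smiles!r}")
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def compute_descriptors(mol_or_smiles) -> dict[str, Optional[float]]:
    """The full 39-member panel; a failed estimator is recorded as None."""
    mol = _as_mol(mol_or_smiles)
    out: dict[str, Optional[float]] = {}
    for name, fn in PANEL.items():
        try:
            value = float(fn(mol))
            out[name] = value if math.isfinite(value) else None
        except Exception:
            out[name] = None
    return out


def lipinski_violations(desc: dict) -> int:
    """Count of Rule-of-Five violations: MW > 500, HBD > 5, HBA > 10, logP > 5.

    Boundary values (exactly 500 / 5 / 10 / 5) comply; only strict excess
    counts.  HBD/HBA use the Lipinski OH+NH / N+O count convention.
    """
    needed = {"AMW": 500, "NHOHCount": 5, "NOCount": 10, "SlogP": 5}
    missing = [k for k in needed if desc.get(k) is None]
    if missing:
        raise DescriptorError(f"missing descriptors for Lipinski rule: {missing}")
    return sum(1 for k, limit in needed.items() if desc[k] > limit)


_catalogs: dict[str, FilterCatalog] = {}


def _catalog(kind: str) -> FilterCatalog:
    if kind not in _catalogs:
        params = FilterCatalogParams()
        params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, kind))
        _catalogs[kind] = FilterCatalog(params)
    return _catalogs[kind]


def _hits(mol_or_smiles, kind: str) -> list[str]:
    mol = _as_mol(mol_or_smiles)
    return sorted({e.GetDescription() for e in _catalog(kind).GetMatches(mol)})


def pains_hits(mol_or_smiles) -> list[str]:
    """Names of matched pan-assay interference (PAINS) patterns; [] = pass."""
    return _hits(mol_or_smiles, "PAINS")


def brenk_hits(mol_or_smiles) -> list[str]:
    """Names of matched Brenk undesirable-substructure patterns; [] = pass."""
    return _hits(mol_or_smiles, "BRENK")


def filter_report(mol_or_smiles) -> dict:
    """Lipinski violation count plus PAINS and Brenk hit lists."""
    mol = _as_mol(mol_or_smiles)
    return {
        "lipinski_violations": lipinski_violations(compute_descriptors(mol)),
        "pains_hits": pains_hits(mol),
        "brenk_hits": brenk_hits(mol),
    }
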