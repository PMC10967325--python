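"""Matched molecular pairs (MMPs) and activity cliffs.

Molecules are fragmented by deleting acyclic single bonds between two
non-hydrogen atoms (single cuts and unordered combinations up to
``max_cuts``), producing key/value records: the *value* is the variable
fragment carrying every numbered attachment point, the *key* is the
remaining context.  Indexing records by key yields candidate pairs; pairs
must satisfy an ECFP4 Tanimoto > 0.56 and differ by at most 10 heavy atoms,
and a transformation is kept only when observed in at least four distinct
pairs.  Explicit hydrogens are removed and stereochemistry is ignored
during fragmentation.

Each pair falls into one of four categories driven by the literal
concentration rule with d = |IC50_a - IC50_b|:

* activity cliff      — at least one partner active and d >= 100 nM
* similarly active    — both active and d < 100 nM
* similarly inactive  — both inactive and d < 100 nM
* soft cliff          — one partner active and d < 100 nM

Pairs with both partners inactive but d >= 100 nM stay uncategorized.
"""

from __future__ import annotations

import itertools
import statistics as pystats
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem

from .curation import ACTIVITY_THRESHOLD, MoleculeRecord
from .similarity import Fingerprint, fingerprint, tanimoto

__all__ = [
    "FragmentationRecord",
    "MatchedPair",
    "TransformationStats",
    "MMPConfig",
    "fragment_molecule",
    "reassemble",
    "find_pairs",
    "categorize_pair",
    "transformation_stats",
    "cliff_fragments",
    "run_mmp_analysis",
]

CATEGORIES = (
    "activity_cliff",
    "soft_cliff",
    "similarly_active",
    "similarly_inactive",
    "uncategorized",
)


@dataclass
class MMPConfig:
    max_cuts: int = 2
    tc_gate: float = 0.56  # strict: similarity must exceed this
    max_heavy_diff: int = 10
    min_transformation_pairs: int = 4
    cliff_ic50_diff: float = 1.0e-7  # molar (100 nM), the literal rule
    cliff_rule: str = "ic50_difference"  # | "delta_pic50" | "fold_change"
    cliff_delta_pic50: float = 1.0  # used when cliff_rule == "delta_pic50"
    cliff_fold_change: float = 10.0  # used when cliff_rule == "fold_change"
    activity_threshold: float = ACTIVITY_THRESHOLD
    filter_min_pairs: int = 10
    filter_min_cliff_fraction: float = 0.05


@dataclass
class FragmentationRecord:
    molecule_id: str
    key: str  # context fragment(s), '.'-joined canonical SMILES with [*:n]
    value: str  # variable fragment with matching attachment points
    n_cuts: int


@dataclass
class MatchedPair:
    id_a: str
    id_b: str
    key: str
    transformation: str  # "valueA>>valueB", valueA lexicographically smaller
    similarity: float
    heavy_atom_diff: int
    delta_pic50: float  # pic50(b) - pic50(a)
    category: str = ""


@dataclass
class TransformationStats:
    transformation: str
    n_pairs: int
    n_cliffs: int
    cliff_fraction: float
    mean_abs_delta: float
    passes_filter: bool


class FragmentationError(ValueError):
    pass


def _prepare(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.RemoveHs(mol)
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    return mol


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        out.append(bond.GetIdx())
    return out


def _split(mol: Chem.Mol, bond_ids: Sequence[int]):
    frag = Chem.FragmentOnBonds(
        mol, list(bond_ids), addDummies=True,
        dummyLabels=[(i + 1, i + 1) for i in range(len(bond_ids))],
    )
    # FragmentOnBonds marks dummies via isotope; move the label to atom maps
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope():
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    return pieces


def _dummy_maps(piece: Chem.Mol) -> list[int]:
    return [a.GetAtomMapNum() for a in piece.GetAtoms() if a.GetAtomicNum() == 0]


def _canonical_with_renumber(value: Chem.Mol, keys: list[Chem.Mol]) -> tuple[str, str]:
    """Renumber attachment maps by the value fragment's canonical atom order,
    apply the same relabeling to the key fragments, return (key, value) SMILES."""
    k = len(_dummy_maps(value))
    if k == 1:
        relabel = {_dummy_maps(value)[0]: 1}
    else:
        bare = Chem.Mol(value)
        for a in bare.GetAtoms():
            a.SetAtomMapNum(0)
        ranks = list(Chem.CanonicalRankAtoms(bare, breakTies=True))
        dummies = [
            (ranks[a.GetIdx()], a.GetAtomMapNum())
            for a in value.GetAtoms()
            if a.GetAtomicNum() == 0
        ]
        relabel = {old: new + 1 for new, (_, old) in enumerate(sorted(dummies))}

    def apply(m: Chem.Mol) -> str:
        m = Chem.Mol(m)
        for a in m.GetAtoms():
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum():
                a.SetAtomMapNum(relabel[a.GetAtomMapNum()])
        return Chem.MolToSmiles(m)

    key_smiles = ".".join(sorted(apply(km) for km in keys))
    return key_smiles, apply(value)


def fragment_molecule(
    mol_or_smiles, molecule_id: str = "", max_cuts: int = 2
) -> list[FragmentationRecord]:
    """All key/value fragmentations with 1..max_cuts cuts.

    Only acyclic single bonds between heavy atoms are cut.  One record per
    cut combination: for a single cut the smaller fragment is the variable
    part; for multiple cuts the value is the unique fragment touching every
    cut bond (when none exists the cut combination yields no record).
    Molecules with no eligible bond return an empty list.
    """
    mol = mol_or_smiles
    if not isinstance(mol, Chem.Mol):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise FragmentationError(f"unparsable SMILES: {mol_or_smiles!r}")
    mol = _prepare(mol)
    bonds = _cuttable_bonds(mol)
    records: list[FragmentationRecord] = []
    for k in range(1, max_cuts + 1):
        for combo in itertools.combinations(bonds, k):
            pieces = _split(mol, combo)
            full = [p for p in pieces if len(_dummy_maps(p)) == k]
            if k == 1:
                # one record per cut: the smaller fragment is the variable
                # part (localized transformation); ties break on SMILES
                ranked = sorted(
                    range(len(pieces)),
                    key=lambda j: (pieces[j].GetNumHeavyAtoms(), Chem.MolToSmiles(pieces[j])),
                )
                vi = ranked[0]
                keys = [p for j, p in enumerate(pieces) if j != vi]
                key_s, value_s = _canonical_with_renumber(pieces[vi], keys)
                records.append(FragmentationRecord(molecule_id, key_s, value_s, k))
            else:
                if len(full) != 1:
                    continue
                value = full[0]
                keys = [p for p in pieces if p is not value]
                key_s, value_s = _canonical_with_renumber(value, keys)
                records.append(FragmentationRecord(molecule_id, key_s, value_s, k))
    return records


def reassemble(record: FragmentationRecord) -> str:
    """Rebuild the parent canonical SMILES from a key/value record."""
    combined = Chem.MolFromSmiles(record.value)
    for part in record.key.split("."):
        combined = Chem.CombineMols(combined, Chem.MolFromSmiles(part))
    out = Chem.molzip(combined)
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def find_pairs(
    records: Sequence[MoleculeRecord],
    config: MMPConfig = MMPConfig(),
    fragmentations: Optional[dict[str, list[FragmentationRecord]]] = None,
) -> list[MatchedPair]:
    """Index fragmentations by context key and emit constrained pairs.

    Constraints: different value fragments under a shared key, ECFP4
    Tanimoto > ``tc_gate``, heavy-atom count difference <= ``max_heavy_diff``;
    transformations observed in fewer than ``min_transformation_pairs``
    distinct pairs are discarded.  Each unordered molecule pair appears once
    per distinct transformation, in canonical direction (lexicographically
    smaller value fragment first, delta_pic50 signed accordingly).
    """
    by_id = {r.id: r for r in records}
    mols = {r.id: Chem.MolFromSmiles(r.smiles or r.smiles_raw) for r in records}
    if fragmentations is None:
        fragmentations = {
            r.id: fragment_molecule(mols[r.id], r.id, config.max_cuts) for r in records
        }
    fps: dict[str, Fingerprint] = {}
    heavy = {rid: m.GetNumHeavyAtoms() for rid, m in mols.items()}

    index: dict[str, dict[str, set[str]]] = {}
    for rid, recs in fragmentations.items():
        for fr in recs:
            index.setdefault(fr.key, {}).setdefault(fr.value, set()).add(rid)

    candidates: dict[tuple[str, str, str], MatchedPair] = {}
    for key, by_value in index.items():
        if len(by_value) < 2:
            continue
        values = sorted(by_value)
        for va, vb in itertools.combinations(values, 2):
            for ra in by_value[va]:
                for rb in by_value[vb]:
                    if ra == rb:
                        continue
                    id_a, id_b, fa, fb = (ra, rb, va, vb)
                    if abs(heavy[id_a] - heavy[id_b]) > config.max_heavy_diff:
                        continue
                    for rid in (id_a, id_b):
                        if rid not in fps:
                            fps[rid] = fingerprint(mols[rid])
                    sim = tanimoto(fps[id_a], fps[id_b])
                    if not sim > config.tc_gate:
                        continue
                    transformation = f"{fa}>>{fb}"
                    pair_key = (min(id_a, id_b), max(id_a, id_b), transformation)
                    if pair_key in candidates:
                        continue
                    delta = (by_id[id_b].pic50 or 0.0) - (by_id[id_a].pic50 or 0.0)
                    candidates[pair_key] = MatchedPair(
                        id_a=id_a, id_b=id_b, key=key, transformation=transformation,
                        similarity=sim, heavy_atom_diff=abs(heavy[id_a] - heavy[id_b]),
                        delta_pic50=delta,
                    )

    counts: dict[str, int] = {}
    for pair in candidates.values():
        counts[pair.transformation] = counts.get(pair.transformation, 0) + 1
    pairs = [
        p for p in candidates.values()
        if counts[p.transformation] >= config.min_transformation_pairs
    ]
    for pair in pairs:
        pair.category = categorize_pair(
            by_id[pair.id_a].pic50, by_id[pair.id_b].pic50, config
        )
    return sorted(pairs, key=lambda p: (p.id_a, p.id_b, p.transformation))


def _activity_difference_crosses(pic50_a: float, pic50_b: float, config: MMPConfig) -> bool:
    if config.cliff_rule == "ic50_difference":
        d = abs(10.0 ** (-pic50_a) - 10.0 ** (-pic50_b))
        return d >= config.cliff_ic50_diff
    if config.cliff_rule == "delta_pic50":
        return abs(pic50_a - pic50_b) >= config.cliff_delta_pic50
    if config.cliff_rule == "fold_change":
        hi, lo = max(pic50_a, pic50_b), min(pic50_a, pic50_b)
        return 10.0 ** (hi - lo) >= config.cliff_fold_change
    raise ValueError(f"unknown cliff rule {config.cliff_rule!r}")


def categorize_pair(
    pic50_a: Optional[float], pic50_b: Optional[float], config: MMPConfig = MMPConfig()
) -> str:
    """Assign the four-way cliff taxonomy (fixed evaluation order)."""
    if pic50_a is None or pic50_b is None:
        raise ValueError("both pIC50 values are required to categorize a pair")
    t = config.activity_threshold
    active_a, active_b = pic50_a >= t, pic50_b >= t
    crosses = _activity_difference_crosses(pic50_a, pic50_b, config)
    if (active_a or active_b) and crosses:
        return "activity_cliff"
    if active_a and active_b and not crosses:
        return "similarly_active"
    if not active_a and not active_b and not crosses:
        return "similarly_inactive"
    if (active_a or active_b) and not crosses:
        return "soft_cliff"
    return "uncategorized"


def transformation_stats(
    pairs: Sequence[MatchedPair], config: MMPConfig = MMPConfig()
) -> list[TransformationStats]:
    """Aggregate categorized pairs per transformation and apply the
    frequent-cliff filter (>= 10 pairs and >= 5 % cliffs by default)."""
    groups: dict[str, list[MatchedPair]] = {}
    for p in pairs:
        groups.setdefault(p.transformation, []).append(p)
    out = []
    for t, ps in sorted(groups.items()):
        n = len(ps)
        n_cliffs = sum(1 for p in ps if p.category == "activity_cliff")
        frac = n_cliffs / n
        out.append(
            TransformationStats(
                transformation=t,
                n_pairs=n,
                n_cliffs=n_cliffs,
                cliff_fraction=frac,
                mean_abs_delta=float(
                    sum(abs(p.delta_pic50) for p in ps) / n
                ),
                passes_filter=(
                    n >= config.filter_min_pairs
                    and frac >= config.filter_min_cliff_fraction
                ),
            )
        )
    return out


def _cap_attachment_points(frag_smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(frag_smiles)
    if mol is None:
        return None
    em = Chem.RWMol(mol)
    for atom in em.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    mol = Chem.RemoveHs(em.GetMol())
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol) if mol.GetNumAtoms() else None


def cliff_fragments(passing: Sequence[TransformationStats]) -> dict:
    """Unique fragments on either side of filter-passing transformations,
    with a physicochemical summary computed on H-capped fragments."""
    from .descriptors import compute_descriptors

    frags: set[str] = set()
    for t in passing:
        if not t.passes_filter:
            continue
        a, b = t.transformation.split(">>")
        frags.update((a, b))
    frags = sorted(frags)
    slogp = []
    rows = []
    for f in frags:
        capped = _cap_attachment_points(f)
        desc = compute_descriptors(capped) if capped else {}
        rows.append({"fragment": f, "capped": capped, "SlogP": desc.get("SlogP")})
        if desc.get("SlogP") is not None:
            slogp.append(desc["SlogP"])
    return {
        "fragments": frags,
        "n_unique": len(frags),
        "median_slogp": float(pystats.median(slogp)) if slogp else None,
        "table": rows,
    }


def run_mmp_analysis(
    records: Sequence[MoleculeRecord], config: MMPConfig = MMPConfig()
) -> dict:
    """Pairs, category counts, transformation stats, and cliff fragments."""
    pairs = find_pairs(records, config)
    stats = transformation_stats(pairs, config)
    passing = [t for t in stats if t.passes_filter]
    category_counts = {c: sum(1 for p in pairs if p.category == c) for c in CATEGORIES}
    return {
        "pairs": pairs,
        "transformation_stats": stats,
        "n_pairs": len(pairs),
        "n_transformations": len(stats),
        "n_passing_transformations": len(passing),
        "category_counts": category_counts,
        "cliff_fragments": cliff_fragments(passing),
    }
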