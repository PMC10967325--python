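"""Synthetic ENR-inhibitor benchmark datasets with planted ground truth.

Molecules are enumerated from ring-system scaffold templates carrying
numbered attachment points; substituents from an R-group table are zipped
onto the attachment points.  Activity follows an additive model in pIC50
space

    pIC50 = baseline(scaffold) + sum_p contribution(substituent at p)
            + cliff bonus(scaffold, position, substituent) + N(0, noise_sd)

so every single-substituent matched pair, and every activity cliff driven by
a context-specific cliff rule, is known by construction.  The defaults mimic
the statistical shape of a curated ENR inhibitor collection: four enzyme
datasets of very unequal size (1000/445/51/15 for InhA/FabI/FabK/FabV),
pIC50 spanning roughly 3.5-9.7 with a 5.5 activity threshold, skewed
scaffold frequencies, and a fraction of records reported only as
"qualitative inactive" with no numeric IC50.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import ACTIVITY_THRESHOLD, MoleculeRecord

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "PlantedPair",
    "default_spec",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]


class TemplateError(ValueError):
    """A scaffold or substituent SMILES does not parse or lacks attachment points."""


class CapacityError(ValueError):
    """More unique molecules requested than the template space can enumerate."""


#: Cliff-rule defaults place a large context-specific bonus (|value| >= 2
#: pIC50 units) on particular (scaffold, position, substituent) combinations.
DEFAULT_SCAFFOLDS = [
    "c1cc([*:1])ccc1Oc1cccc([*:2])c1",          # diphenyl ether (para/meta)
    "c1cc([*:1])ccc1-c1cccc([*:2])c1",          # biphenyl (para/meta)
    "c1cc([*:1])ccc1Cc1cccc([*:2])c1",          # diphenylmethane (para/meta)
    "c1cc([*:1])ccc1Nc1cccc([*:2])c1",          # diphenylamine (para/meta)
    "c1cc([*:1])ccc1-c1ccc([*:2])cn1",          # 2-phenylpyridine
    "c1cc([*:1])ccc1C(=O)Nc1ccc([*:2])cc1",     # benzanilide
    "c1cc([*:1])ccc1Oc1ccc([*:2])cn1",          # phenoxypyridine
    "c1cc([*:1])ccc1S(=O)(=O)Nc1ccc([*:2])cc1", # benzenesulfonanilide
]

DEFAULT_WEIGHTS = [0.30, 0.22, 0.16, 0.12, 0.08, 0.06, 0.04, 0.02]

DEFAULT_BASELINES = [5.7, 5.0, 4.7, 4.4, 5.3, 4.2, 4.8, 5.5]

#: Substituent SMILES (attachment written as [*:1]; remapped per position)
#: and their additive pIC50 contributions.
DEFAULT_RGROUPS = {
    "[*:1]OCC": 0.0,
    "[*:1]C": 0.2,
    "[*:1]CC": 0.3,
    "[*:1]O": -0.2,
    "[*:1]OC": 0.1,
    "[*:1]Cl": 0.4,
    "[*:1]F": 0.1,
    "[*:1]Br": 0.5,
    "[*:1]C(F)(F)F": 0.6,
    "[*:1]C#N": -0.3,
    "[*:1]N": -0.4,
    "[*:1]C(C)C": 0.3,
}

#: (scaffold index, position, substituent SMILES) -> extra pIC50.
DEFAULT_CLIFF_RULES = {
    (0, 1, "[*:1]OC"): 2.5,
    (1, 2, "[*:1]C(F)(F)F"): 2.6,
    (3, 1, "[*:1]Cl"): 2.2,
}

DEFAULT_N_PER_ENZYME = {"InhA": 1000, "FabI": 445, "FabK": 51, "FabV": 15}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic benchmark dataset."""

    scaffold_templates: list[str] = field(default_factory=lambda: list(DEFAULT_SCAFFOLDS))
    scaffold_weights: list[float] = field(default_factory=lambda: list(DEFAULT_WEIGHTS))
    rgroup_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RGROUPS))
    cliff_rules: dict[tuple[int, int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CLIFF_RULES)
    )
    baseline: list[float] = field(default_factory=lambda: list(DEFAULT_BASELINES))
    noise_sd: float = 0.3
    n_per_enzyme: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_ENZYME))
    qualitative_fraction: float = 0.10
    activity_threshold: float = ACTIVITY_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        if len(self.scaffold_templates) != len(self.scaffold_weights) or len(
            self.scaffold_templates
        ) != len(self.baseline):
            raise ValueError("templates, weights and baselines must align")
        if any(w <= 0 for w in self.scaffold_weights):
            raise ValueError("scaffold weights must be positive")
        if any(n < 1 for n in self.n_per_enzyme.values()):
            raise ValueError("n_per_enzyme values must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.qualitative_fraction <= 1:
            raise ValueError("qualitative_fraction must be in [0, 1]")
        for (si, pos, sub), bonus in self.cliff_rules.items():
            if not 0 <= si < len(self.scaffold_templates):
                raise ValueError(f"cliff rule references unknown scaffold index {si}")
            if sub not in self.rgroup_table:
                raise ValueError(f"cliff rule references unknown substituent {sub!r}")
            if pos not in _attachment_positions(self.scaffold_templates[si]):
                raise ValueError(f"cliff rule references missing position {pos} on scaffold {si}")


@dataclass
class PlantedPair:
    """A ground-truth matched pair differing by one substituent."""

    id_a: str
    id_b: str
    enzyme: str
    scaffold_index: int
    position: int
    sub_a: str
    sub_b: str
    delta_pic50: float  # pic50(b) - pic50(a), noise-free
    is_cliff: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that downstream stages must recover."""

    expected_scaffold_counts: dict[str, dict[str, int]]  # enzyme -> murcko smiles -> n
    planted_pairs: list[PlantedPair]
    planted_cliffs: list[PlantedPair]
    pic50_true: dict[str, float]  # record id -> noise-free pIC50 (post-imputation)
    scaffold_murcko: list[str]  # per template index


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    spec = SyntheticSpec(seed=seed)
    for key, value in overrides.items():
        setattr(spec, key, value)
    return spec


def _attachment_positions(template: str) -> list[int]:
    mol = Chem.MolFromSmiles(template)
    if mol is None:
        raise TemplateError(f"invalid scaffold template SMILES: {template!r}")
    pos = sorted(
        a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum()
    )
    if not pos:
        raise TemplateError(f"scaffold template has no numbered attachment points: {template!r}")
    return pos


def _substituent_mol(sub_smiles: str, position: int) -> Chem.Mol:
    mol = Chem.MolFromSmiles(sub_smiles, sanitize=False)
    if mol is None:
        raise TemplateError(f"invalid substituent SMILES: {sub_smiles!r}")
    mol = Chem.RWMol(mol)
    n_dummy = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            atom.SetAtomMapNum(position)
            n_dummy += 1
    if n_dummy != 1:
        raise TemplateError(f"substituent must have exactly one attachment point: {sub_smiles!r}")
    return mol.GetMol()


def assemble(template: str, substituents: dict[int, str]) -> str:
    """Zip substituents onto a scaffold template; return canonical SMILES."""
    scaffold = Chem.MolFromSmiles(template)
    if scaffold is None:
        raise TemplateError(f"invalid scaffold template SMILES: {template!r}")
    combined = scaffold
    for pos, sub in substituents.items():
        combined = Chem.CombineMols(combined, _substituent_mol(sub, pos))
    zipped = Chem.molzip(combined)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def _murcko_of_template(template: str) -> str:
    from rdkit.Chem.Scaffolds import MurckoScaffold

    positions = _attachment_positions(template)
    smiles = assemble(template, {p: "[*:1][H]" for p in positions})
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def generate_dataset(spec: SyntheticSpec) -> tuple[list[MoleculeRecord], GroundTruth]:
    """Generate records plus the ground truth used by the acceptance checks.

    Identical spec + seed gives byte-identical output.  Raises
    :class:`CapacityError` when an enzyme requests more unique molecules than
    the scaffold x substituent space can enumerate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    positions = [_attachment_positions(t) for t in spec.scaffold_templates]
    subs = sorted(spec.rgroup_table)
    murckos = [_murcko_of_template(t) for t in spec.scaffold_templates]

    # Per-scaffold pre-shuffled combo decks: uniform sampling w/o replacement.
    decks: list[list[tuple[str, ...]]] = []
    for si in range(len(spec.scaffold_templates)):
        combos = list(itertools.product(subs, repeat=len(positions[si])))
        rng.shuffle(combos)
        decks.append(combos)
    capacity = sum(len(d) for d in decks)
    max_n = max(spec.n_per_enzyme.values())
    if max_n > capacity:
        raise CapacityError(
            f"requested {max_n} unique molecules but only {capacity} are enumerable"
        )

    weights = np.asarray(spec.scaffold_weights, dtype=float)
    weights = weights / weights.sum()

    records: list[MoleculeRecord] = []
    pic50_true: dict[str, float] = {}
    scaffold_counts: dict[str, dict[str, int]] = {}
    by_enzyme_molecules: dict[str, list[tuple[str, int, tuple[str, ...]]]] = {}

    for enzyme in sorted(spec.n_per_enzyme):
        n = spec.n_per_enzyme[enzyme]
        used: list[int] = [0] * len(decks)  # per-scaffold deck cursor
        counts: dict[str, int] = {}
        molecules: list[tuple[str, int, tuple[str, ...]]] = []
        seen: set[str] = set()

        def pop_unique(si: int):
            # symmetric scaffolds can map distinct combos to one canonical
            # molecule; skip those so every emitted structure is unique
            while used[si] < len(decks[si]):
                combo = decks[si][used[si]]
                used[si] += 1
                smiles = assemble(
                    spec.scaffold_templates[si], dict(zip(positions[si], combo))
                )
                if smiles not in seen:
                    return combo, smiles
            return None

        for i in range(n):
            si = int(rng.choice(len(weights), p=weights))
            drawn = pop_unique(si)
            while drawn is None:
                avail = [j for j in range(len(decks)) if used[j] < len(decks[j])]
                if not avail:
                    raise CapacityError("template space exhausted during sampling")
                w = weights[avail] / weights[avail].sum()
                si = int(avail[int(rng.choice(len(avail), p=w))])
                drawn = pop_unique(si)
            combo, smiles = drawn
            seen.add(smiles)

            mol_id = f"{enzyme}-{i:05d}"
            sub_map = dict(zip(positions[si], combo))
            base = spec.baseline[si]
            contrib = sum(spec.rgroup_table[s] for s in combo)
            bonus = sum(
                spec.cliff_rules.get((si, p, s), 0.0) for p, s in sub_map.items()
            )
            value = base + contrib + bonus
            noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
            pic50 = value + noise

            qualitative = (
                pic50 < spec.activity_threshold
                and spec.qualitative_fraction > 0
                and float(rng.random()) < spec.qualitative_fraction
            )
            if qualitative:
                record = MoleculeRecord(
                    id=mol_id, smiles_raw=smiles, enzyme=enzyme, ic50=None,
                    qualitative_inactive=True, source="synthetic",
                )
                pic50_true[mol_id] = 4.0  # post-imputation value
            else:
                record = MoleculeRecord(
                    id=mol_id, smiles_raw=smiles, enzyme=enzyme,
                    ic50=float(10.0 ** (-pic50)), source="synthetic",
                )
                pic50_true[mol_id] = value if spec.noise_sd == 0 else pic50
            records.append(record)
            molecules.append((mol_id, si, combo))
            counts[murckos[si]] = counts.get(murckos[si], 0) + 1
        scaffold_counts[enzyme] = counts
        by_enzyme_molecules[enzyme] = molecules

    pairs, cliffs = _enumerate_planted_pairs(
        spec, positions, by_enzyme_molecules, pic50_true
    )
    truth = GroundTruth(
        expected_scaffold_counts=scaffold_counts,
        planted_pairs=pairs,
        planted_cliffs=cliffs,
        pic50_true=pic50_true,
        scaffold_murcko=murckos,
    )
    return records, truth


def _enumerate_planted_pairs(spec, positions, by_enzyme, pic50_true):
    """All same-enzyme, same-scaffold pairs differing at exactly one position."""
    pairs: list[PlantedPair] = []
    cliffs: list[PlantedPair] = []
    for enzyme, molecules in sorted(by_enzyme.items()):
        # index by (scaffold, position varied, fixed context of other subs)
        for si in {m[1] for m in molecules}:
            mols = [m for m in molecules if m[1] == si]
            pos = positions[si]
            for vary_idx, vary_pos in enumerate(pos):
                groups: dict[tuple, list] = {}
                for mol_id, _, combo in mols:
                    ctx = combo[:vary_idx] + combo[vary_idx + 1 :]
                    groups.setdefault(ctx, []).append((mol_id, combo[vary_idx]))
                for members in groups.values():
                    members.sort()
                    for (id_a, sub_a), (id_b, sub_b) in itertools.combinations(members, 2):
                        if sub_a == sub_b:
                            continue
                        delta = pic50_true[id_b] - pic50_true[id_a]
                        pair = PlantedPair(
                            id_a=id_a, id_b=id_b, enzyme=enzyme, scaffold_index=si,
                            position=vary_pos, sub_a=sub_a, sub_b=sub_b,
                            delta_pic50=delta,
                            is_cliff=_is_cliff(
                                pic50_true[id_a], pic50_true[id_b], spec.activity_threshold
                            ),
                        )
                        pairs.append(pair)
                        if pair.is_cliff:
                            cliffs.append(pair)
    return pairs, cliffs


def _is_cliff(pic50_a: float, pic50_b: float, threshold: float) -> bool:
    """Literal concentration rule: one partner active and |dIC50| >= 100 nM."""
    active = pic50_a >= threshold or pic50_b >= threshold
    d = abs(10.0 ** (-pic50_a) - 10.0 ** (-pic50_b))
    return active and d >= 1.0e-7


# ---------------------------------------------------------------------------
# ground-truth recovery scoring


def recovery_report(curated_records, truth: GroundTruth, mmp_config=None) -> dict:
    """Score the matched-pair stage against the planted ground truth.

    A planted pair is *eligible* when it independently satisfies the pair
    constraints: ECFP4 Tanimoto above the gate, heavy-atom difference within
    the limit, and its substituent transformation observed in at least the
    minimum number of eligible pairs (computed here by direct enumeration,
    not by the matched-pair engine).  Reports the recovered fraction of
    eligible pairs and, among recovered pairs, the confusion between planted
    cliff labels and the engine's activity-cliff category.
    """
    from rdkit import Chem as _Chem

    from . import mmp as mmp_mod
    from .similarity import fingerprint, tanimoto

    config = mmp_config or mmp_mod.MMPConfig()
    by_id = {r.id: r for r in curated_records}
    result = mmp_mod.run_mmp_analysis(curated_records, config)
    found = {(min(p.id_a, p.id_b), max(p.id_a, p.id_b)): p for p in result["pairs"]}

    fps: dict[str, object] = {}
    heavy: dict[str, int] = {}

    def _fp(rid):
        if rid not in fps:
            mol = _Chem.MolFromSmiles(by_id[rid].smiles or by_id[rid].smiles_raw)
            fps[rid] = fingerprint(mol)
            heavy[rid] = mol.GetNumHeavyAtoms()
        return fps[rid]

    candidates = []
    for pair in truth.planted_pairs:
        if pair.id_a not in by_id or pair.id_b not in by_id:
            continue
        sim = tanimoto(_fp(pair.id_a), _fp(pair.id_b))
        if not sim > config.tc_gate:
            continue
        if abs(heavy[pair.id_a] - heavy[pair.id_b]) > config.max_heavy_diff:
            continue
        candidates.append(pair)
    freq: dict[tuple, int] = {}
    for pair in candidates:
        key = (pair.enzyme,) + tuple(sorted((pair.sub_a, pair.sub_b)))
        freq[key] = freq.get(key, 0) + 1
    eligible = [
        p for p in candidates
        if freq[(p.enzyme,) + tuple(sorted((p.sub_a, p.sub_b)))]
        >= config.min_transformation_pairs
    ]

    n_recovered = 0
    cliff_tp = cliff_fp = cliff_fn = cliff_tn = 0
    for pair in eligible:
        key = (min(pair.id_a, pair.id_b), max(pair.id_a, pair.id_b))
        hit = found.get(key)
        if hit is None:
            continue
        n_recovered += 1
        predicted = hit.category == "activity_cliff"
        if pair.is_cliff and predicted:
            cliff_tp += 1
        elif pair.is_cliff:
            cliff_fn += 1
        elif predicted:
            cliff_fp += 1
        else:
            cliff_tn += 1
    return {
        "n_planted": len(truth.planted_pairs),
        "n_eligible": len(eligible),
        "n_recovered": n_recovered,
        "recovery_fraction": n_recovered / len(eligible) if eligible else None,
        "cliff_true_positive": cliff_tp,
        "cliff_false_positive": cliff_fp,
        "cliff_false_negative": cliff_fn,
        "cliff_true_negative": cliff_tn,
        "cliff_exact": cliff_fp == 0 and cliff_fn == 0,
        "n_found_pairs_total": len(found),
    }


# ---------------------------------------------------------------------------
# I/O

def write_dataset(records: list[MoleculeRecord], path: str | Path, format: str = "csv") -> Path:
    """Write records as CSV (`id,smiles,enzyme,ic50_nM,...`) or SDF."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(
            {
                "id": [r.id for r in records],
                "smiles": [r.smiles_raw for r in records],
                "enzyme": [r.enzyme for r in records],
                "ic50_nM": [None if r.ic50 is None else r.ic50 * 1e9 for r in records],
                "qualitative_inactive": [r.qualitative_inactive for r in records],
                "source": [r.source for r in records],
            }
        )
        df.to_csv(path, index=False)
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in records:
                mol = Chem.MolFromSmiles(r.smiles_raw)
                mol.SetProp("_Name", r.id)
                mol.SetProp("id", r.id)
                mol.SetProp("enzyme", r.enzyme)
                if r.ic50 is not None:
                    mol.SetProp("ic50_nM", repr(r.ic50 * 1e9))
                mol.SetProp("qualitative_inactive", str(r.qualitative_inactive))
                mol.SetProp("source", r.source)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'sdf'")
    return path


def read_dataset(path: str | Path, format: Optional[str] = None) -> list[MoleculeRecord]:
    from . import curation

    path = Path(path)
    fmt = format or ("sdf" if path.suffix.lower() == ".sdf" else "csv")
    return curation.read_sdf(path) if fmt == "sdf" else curation.read_csv(path)
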