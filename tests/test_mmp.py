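"""Matched-pair mining: fragmentation round-trips and exhaustive-enumeration
equivalence, pair constraints, the four-way cliff taxonomy, and the
frequent-cliff transformation filter."""

import itertools

import pytest
from rdkit import Chem

from enrspace.curation import MoleculeRecord
from enrspace.mmp import (
    CATEGORIES,
    FragmentationError,
    MatchedPair,
    MMPConfig,
    categorize_pair,
    cliff_fragments,
    find_pairs,
    fragment_molecule,
    reassemble,
    transformation_stats,
)
from enrspace import synthetic


def eligible_bonds(smiles):
    mol = Chem.MolFromSmiles(smiles)
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


class TestFragmentation:
    def test_ethylbenzene_single_cuts(self):
        records = fragment_molecule("CCc1ccccc1", max_cuts=1)
        assert len(records) == 2  # Ph-C and C-C cuts
        values = {r.value for r in records}
        assert values == {"C[*:1]", "CC[*:1]"}

    def test_methane_empty(self):
        assert fragment_molecule("C") == []

    def test_benzene_no_eligible_bonds(self):
        assert fragment_molecule("c1ccccc1") == []

    def test_unparsable(self):
        with pytest.raises(FragmentationError):
            fragment_molecule("((bad")

    @pytest.mark.parametrize(
        "smiles",
        ["CCc1ccccc1", "Cc1ccc(O)cc1", "CC(C)Oc1ccc(Cl)cc1", "CCOC(=O)c1ccccn1"],
    )
    def test_round_trip(self, smiles):
        canonical = Chem.CanonSmiles(smiles)
        for record in fragment_molecule(smiles, max_cuts=2):
            assert reassemble(record) == canonical

    @pytest.mark.parametrize("smiles", ["CCOc1ccccc1", "CC(C)CC(N)=O", "CCCCCCCCCC"])
    def test_exhaustive_enumeration_equivalence(self, smiles):
        """Every eligible bond subset of size <= max_cuts yields exactly one
        record when a valid variable fragment exists (single cuts always do;
        double cuts need a middle fragment touching both bonds)."""
        bonds = eligible_bonds(smiles)
        records = fragment_molecule(smiles, max_cuts=2)
        n_single = sum(1 for r in records if r.n_cuts == 1)
        n_double = sum(1 for r in records if r.n_cuts == 2)
        assert n_single == len(bonds)
        # count two-cut combinations with a middle fragment by brute force
        mol = Chem.MolFromSmiles(smiles)
        expected_double = 0
        for combo in itertools.combinations(bonds, 2):
            frag = Chem.FragmentOnBonds(mol, list(combo), addDummies=True)
            pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
            with_two = [
                p
                for p in pieces
                if sum(1 for a in p.GetAtoms() if a.GetAtomicNum() == 0) == 2
            ]
            if len(with_two) == 1:
                expected_double += 1
        assert n_double == expected_double

    def test_round_trip_on_synthetic_molecules(self):
        spec = synthetic.default_spec(
            seed=23, n_per_enzyme={"InhA": 12}, noise_sd=0.0, qualitative_fraction=0.0
        )
        records, _ = synthetic.generate_dataset(spec)
        for r in records:
            canonical = Chem.CanonSmiles(r.smiles_raw)
            frags = fragment_molecule(r.smiles_raw, max_cuts=2)
            assert frags
            for fr in frags:
                assert reassemble(fr) == canonical


def record(rid, smiles, pic50, enzyme="InhA"):
    return MoleculeRecord(
        id=rid, smiles_raw=smiles, smiles=Chem.CanonSmiles(smiles),
        enzyme=enzyme, pic50=pic50,
    )


class TestFindPairs:
    def test_single_substituent_change_detected(self):
        a = record("a", "Cc1ccc(O)cc1", 6.0)
        b = record("b", "Clc1ccc(O)cc1", 5.0)
        cfg = MMPConfig(min_transformation_pairs=1, tc_gate=0.0)
        pairs = find_pairs([a, b], cfg)
        assert any(p.transformation == "C[*:1]>>Cl[*:1]" for p in pairs)

    def test_identical_molecules_no_pair(self):
        a = record("a", "Cc1ccc(O)cc1", 6.0)
        b = record("b", "Cc1ccc(O)cc1", 6.5)
        cfg = MMPConfig(min_transformation_pairs=1, tc_gate=0.0)
        assert find_pairs([a, b], cfg) == []

    def test_order_independence(self):
        mols = [
            record("a", "Cc1ccc(O)cc1Oc1ccccc1", 6.0),
            record("b", "Clc1ccc(O)cc1Oc1ccccc1", 5.0),
            record("c", "Brc1ccc(O)cc1Oc1ccccc1", 7.0),
        ]
        cfg = MMPConfig(min_transformation_pairs=1, tc_gate=0.0)
        forward = find_pairs(mols, cfg)
        backward = find_pairs(list(reversed(mols)), cfg)
        assert forward == backward

    def test_tc_gate_is_strict(self):
        a = record("a", "Cc1ccc(O)cc1", 6.0)
        b = record("b", "Clc1ccc(O)cc1", 5.0)
        pairs = find_pairs([a, b], MMPConfig(min_transformation_pairs=1, tc_gate=0.99))
        assert pairs == []

    def test_matches_brute_force_on_small_set(self):
        """Pair set equals an all-pairs common-context search."""
        spec = synthetic.default_spec(
            seed=29, n_per_enzyme={"InhA": 15}, noise_sd=0.0, qualitative_fraction=0.0
        )
        records, _ = synthetic.generate_dataset(spec)
        from enrspace.curation import curate

        curated, _ = curate(records)
        cfg = MMPConfig(min_transformation_pairs=1, tc_gate=0.0, max_heavy_diff=100)
        pairs = find_pairs(curated, cfg)
        got = {(p.id_a, p.id_b, p.transformation) for p in pairs}
        expected = set()
        frags = {r.id: fragment_molecule(r.smiles, r.id, 2) for r in curated}
        for ra, rb in itertools.combinations(curated, 2):
            for fa in frags[ra.id]:
                for fb in frags[rb.id]:
                    if fa.key == fb.key and fa.value != fb.value:
                        va, vb = sorted((fa.value, fb.value))
                        ia, ib = (
                            (ra.id, rb.id) if (va, vb) == (fa.value, fb.value) else (rb.id, ra.id)
                        )
                        expected.add((ia, ib, f"{va}>>{vb}"))
        assert got == expected


class TestCategorize:
    def test_large_ic50_gap_is_cliff(self):
        assert categorize_pair(7.0, 5.0) == "activity_cliff"

    def test_both_active_small_gap(self):
        assert categorize_pair(7.0, 7.05) == "similarly_active"

    def test_both_inactive_small_gap(self):
        assert categorize_pair(4.0, 4.0004) == "similarly_inactive"

    def test_soft_cliff_one_active_small_gap(self):
        # 5.6 (2512 nM) vs 5.45 (3548 nM)... gap > 100 nM; use closer values
        assert categorize_pair(7.0, 6.95) == "similarly_active"
        assert categorize_pair(7.4, 5.49999) == "activity_cliff"

    def test_both_inactive_large_gap_uncategorized(self):
        assert categorize_pair(4.0, 5.0) == "uncategorized"

    def test_missing_activity_error(self):
        with pytest.raises(ValueError):
            categorize_pair(None, 6.0)

    def test_partition_on_synthetic_pairs(self, curated_small):
        sub = [r for r in curated_small if r.enzyme == "InhA"]
        pairs = find_pairs(sub, MMPConfig())
        assert pairs
        counts = {c: sum(1 for p in pairs if p.category == c) for c in CATEGORIES}
        assert sum(counts.values()) == len(pairs)

    def test_alternative_delta_pic50_rule(self):
        cfg = MMPConfig(cliff_rule="delta_pic50", cliff_delta_pic50=1.0)
        assert categorize_pair(7.0, 5.9, cfg) == "activity_cliff"
        assert categorize_pair(7.0, 6.5, cfg) == "similarly_active"


def mk_pairs(transformation, n, n_cliffs, delta=1.0):
    pairs = []
    for i in range(n):
        category = "activity_cliff" if i < n_cliffs else "similarly_active"
        pairs.append(
            MatchedPair(
                id_a=f"a{i}", id_b=f"b{i}", key="k", transformation=transformation,
                similarity=0.8, heavy_atom_diff=1, delta_pic50=delta, category=category,
            )
        )
    return pairs


class TestTransformationStats:
    def test_passing_filter(self):
        stats = transformation_stats(mk_pairs("A>>B", 12, 1))
        (t,) = stats
        assert t.cliff_fraction == pytest.approx(1 / 12)
        assert t.passes_filter

    def test_too_few_pairs(self):
        (t,) = transformation_stats(mk_pairs("A>>B", 9, 9))
        assert not t.passes_filter

    def test_no_cliffs(self):
        (t,) = transformation_stats(mk_pairs("A>>B", 20, 0))
        assert not t.passes_filter


class TestCliffFragments:
    def test_union_of_sides(self):
        stats = transformation_stats(
            mk_pairs("C[*:1]>>Cl[*:1]", 12, 6) + mk_pairs("C[*:1]>>O[*:1]", 15, 8)
        )
        out = cliff_fragments(stats)
        assert set(out["fragments"]) == {"C[*:1]", "Cl[*:1]", "O[*:1]"}
        assert out["n_unique"] == 3
        assert out["median_slogp"] is not None

    def test_empty_passing_set(self):
        out = cliff_fragments(transformation_stats(mk_pairs("A>>B", 3, 0)))
        assert out["fragments"] == [] and out["n_unique"] == 0
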