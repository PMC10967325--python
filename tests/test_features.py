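"""Substructure fingerprints, leakage-free pruning/splitting, SMOTE geometry,
nested-CV model selection, and exact tree Shapley attributions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from enrspace._treeshap import tree_shap_values
from enrspace.features import (
    CatalogError,
    FeatureError,
    evaluate,
    load_catalog,
    nested_cv_train,
    prune_features,
    shap_explain,
    smote_oversample,
    stratified_split,
    substructure_fingerprint,
    unreliable_classes,
)


@pytest.fixture(scope="module")
def catalog():
    return load_catalog()


class TestCatalog:
    def test_every_pattern_matches_its_documented_example(self):
        from importlib import resources

        text = resources.files("enrspace.data").joinpath("substructure_keys.tsv").read_text()
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, smarts, example = line.split("\t")
            patt = Chem.MolFromSmarts(smarts)
            assert patt is not None, name
            mol = Chem.MolFromSmiles(example)
            assert mol is not None, name
            assert mol.HasSubstructMatch(patt), name

    def test_malformed_catalog_rejected_at_load(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("nitro\tnot(a(smarts\tCC\n")
        with pytest.raises(CatalogError):
            load_catalog(bad)


class TestFingerprint:
    def test_ethane_has_no_aromatic_keys(self, catalog):
        counts = substructure_fingerprint("CC", catalog)
        assert counts["aromatic_carbon"] == 0
        assert counts["benzene_ring"] == 0
        assert counts["alkane_carbon"] == 2

    def test_nitrobenzene_nitro_key(self, catalog):
        counts = substructure_fingerprint("O=[N+]([O-])c1ccccc1", catalog)
        assert counts["nitro"] >= 1

    def test_deterministic_across_dialects(self, catalog):
        a = substructure_fingerprint("Cc1ccccc1O", catalog)
        b = substructure_fingerprint("Oc1ccccc1C", catalog)
        assert a == b


class TestPrune:
    def make(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        return pd.DataFrame(
            {
                "const": 1.0,
                "a": x,
                "a_dup": x,  # Spearman rho = 1 with a
                "b": rng.normal(size=50),
            }
        )

    def test_constant_removed(self):
        _, kept = prune_features(self.make())
        assert "const" not in kept

    def test_duplicate_collapsed(self):
        _, kept = prune_features(self.make())
        assert ("a" in kept) != ("a_dup" in kept)
        assert "b" in kept

    def test_all_invariant_error(self):
        df = pd.DataFrame({"x": [1.0] * 5, "y": [2.0] * 5})
        with pytest.raises(FeatureError):
            prune_features(df)

    def test_kept_columns_subset(self):
        df = self.make()
        reduced, kept = prune_features(df)
        assert set(kept) <= set(df.columns)
        assert list(reduced.columns[-len(kept):]) == kept


class TestSplit:
    def make(self, n=100):
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {
                "id": [f"m{i}" for i in range(n)],
                "enzyme": ["InhA"] * n,
                "activity_class": ["active"] * 60 + ["inactive"] * 40,
                "x": rng.normal(size=n),
            }
        )

    def test_proportions_preserved(self):
        train, test = stratified_split(self.make(), ratio=0.7, seed=0)
        counts = test["activity_class"].value_counts()
        assert abs(counts["active"] - 18) <= 1
        assert abs(counts["inactive"] - 12) <= 1
        assert len(train) + len(test) == 100
        assert set(train["id"]).isdisjoint(test["id"])

    def test_seed_reproducibility(self):
        a = stratified_split(self.make(), seed=5)
        b = stratified_split(self.make(), seed=5)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_tiny_stratum_error(self):
        df = self.make()
        df.loc[0, "enzyme"] = "FabV"
        with pytest.raises(FeatureError, match="FabV"):
            stratified_split(df)


class TestSmote:
    def test_synthetic_points_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [5.0, 5.0], [5.1, 5.2], [4.9, 5.1]])
        y = np.array([0, 0, 1, 1, 1])
        X_out, y_out, mask = smote_oversample(X, y, k=1, seed=0)
        new = X_out[mask]
        assert (y_out[mask] == 0).all()
        # minority pair (0,0)-(1,2): every synthetic point is t*(1,2)
        for p in new:
            t = p[1] / 2.0
            assert np.allclose(p, [t * 1.0, t * 2.0], atol=1e-12)
            assert 0.0 <= t <= 1.0

    def test_balanced_noop(self):
        X = np.arange(20, dtype=float).reshape(10, 2)
        y = np.array([0] * 5 + [1] * 5)
        X_out, y_out, mask = smote_oversample(X, y, k=2, seed=0)
        assert not mask.any()
        assert np.array_equal(X_out, X)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 10 + [1] * 30)
        a = smote_oversample(X, y, k=3, seed=9)
        b = smote_oversample(X, y, k=3, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_class_counts_reach_target(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 3))
        y = np.array([0] * 10 + [1] * 30)
        _, y_out, _ = smote_oversample(X, y, k=3, seed=0)
        assert (y_out == 0).sum() == (y_out == 1).sum() == 30

    def test_k_too_large_error(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 3 + [1] * 7)
        with pytest.raises(FeatureError, match="smaller k"):
            smote_oversample(X, y, k=5)


class TestNestedCV:
    def test_separable_data_high_macro_f1(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (40, 3)), rng.normal(3, 0.3, (40, 3))])
        y = np.array([0] * 40 + [1] * 40)
        model, ev = nested_cv_train(X, y, seed=0, inner_splits=3, outer_splits=5)
        assert np.mean(ev.cv_fold_scores) > 0.95

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 5))
        y = rng.permutation([0] * 60 + [1] * 60)
        _, ev = nested_cv_train(X, y, seed=1, inner_splits=3, outer_splits=5)
        assert abs(np.mean(ev.cv_fold_scores) - 0.5) < 0.15

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = np.array([0, 1] * 30)
        _, e1 = nested_cv_train(X, y, seed=3, inner_splits=3, outer_splits=4)
        _, e2 = nested_cv_train(X, y, seed=3, inner_splits=3, outer_splits=4)
        assert e1.cv_fold_scores == e2.cv_fold_scores
        assert e1.chosen_params == e2.chosen_params

    def test_unreliable_class_flagged(self):
        # class "C" duplicates class "A"'s feature distribution with few
        # samples: the model cannot recover it, mirroring a 15-molecule
        # enzyme dataset excluded from attribution analysis
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(0, 0.3, (50, 3)), rng.normal(4, 0.3, (50, 3)),
             rng.normal(0, 0.3, (8, 3))]
        )
        y = np.array(["A"] * 50 + ["B"] * 50 + ["C"] * 8)
        model = RandomForestClassifier(random_state=0).fit(X, y)
        ev = evaluate(model, X, y)
        # in-sample C may memorize; evaluate on fresh draws instead
        X_new = np.vstack(
            [rng.normal(0, 0.3, (30, 3)), rng.normal(4, 0.3, (30, 3)),
             rng.normal(0, 0.3, (10, 3))]
        )
        y_new = np.array(["A"] * 30 + ["B"] * 30 + ["C"] * 10)
        ev = evaluate(model, X_new, y_new)
        assert "C" in unreliable_classes(ev, floor=0.5)
        assert "B" not in unreliable_classes(ev, floor=0.5)


def brute_force_tree_shap(tree, x, n_features):
    t = tree.tree_

    def cond_exp(S):
        def rec(n):
            if t.children_left[n] < 0:
                v = t.value[n, 0, :]
                return v[1] / v.sum() if v.shape[0] > 1 else v[0]
            f = t.feature[n]
            if f in S:
                child = t.children_left[n] if x[f] <= t.threshold[n] else t.children_right[n]
                return rec(child)
            wl = t.weighted_n_node_samples[t.children_left[n]]
            wr = t.weighted_n_node_samples[t.children_right[n]]
            return (wl * rec(t.children_left[n]) + wr * rec(t.children_right[n])) / (wl + wr)

        return rec(0)

    phi = np.zeros(n_features)
    for i in range(n_features):
        rest = [f for f in range(n_features) if f != i]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                w = (
                    math.factorial(len(S))
                    * math.factorial(n_features - len(S) - 1)
                    / math.factorial(n_features)
                )
                phi[i] += w * (cond_exp(set(S) | {i}) - cond_exp(set(S)))
    return phi


class TestShapley:
    def make_data(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 4, size=(150, 5)).astype(float)
        y = ((X[:, 0] > 1.5) & (X[:, 2] > 0.5)).astype(int)
        return X, y

    def test_matches_brute_force_enumeration(self):
        X, y = self.make_data()
        tree = DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        for row in range(4):
            phi, _ = tree_shap_values(tree, X[row])
            assert np.allclose(phi[0], brute_force_tree_shap(tree, X[row], 5), atol=1e-9)

    def test_local_accuracy_random_forest(self):
        X, y = self.make_data()
        rf = RandomForestClassifier(n_estimators=30, random_state=0).fit(X, y)
        phi, base = tree_shap_values(rf, X[:20])
        pred = rf.predict_proba(X[:20])[:, 1]
        assert np.abs(phi.sum(axis=1) + base - pred).max() < 1e-6

    def test_stump_attributes_only_split_feature(self):
        X, y = self.make_data()
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        f = stump.tree_.feature[0]
        phi, _ = tree_shap_values(stump, X[:10])
        others = np.delete(phi, f, axis=1)
        assert np.allclose(others, 0.0)
        assert np.abs(phi[:, f]).max() > 0

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(200, 6)).astype(float)
        y = (X[:, 3] >= 1).astype(int)  # feature 3 determines the label
        rf = RandomForestClassifier(n_estimators=50, random_state=0).fit(X, y)
        out = shap_explain(rf, X, feature_names=[f"sub{i}" for i in range(6)])
        assert out["summary"]["feature"].iloc[0] == "sub3"

    def test_unsupported_model_error(self):
        from sklearn.linear_model import LogisticRegression

        X, y = self.make_data()
        lr = LogisticRegression().fit(X, y)
        with pytest.raises(TypeError, match="supported"):
            shap_explain(lr, X)
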