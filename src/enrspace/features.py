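"""Substructure-count fingerprints and Shapley-based feature importance.

The stage mirrors a standard bioactivity-classification workflow: count
functional-group substructures per molecule from a named SMARTS catalog,
drop invariant and highly inter-correlated features (Spearman |rho| > 0.7,
train rows only), split 7:3 with stratification, oversample minority
classes with SMOTE, select a model by nested cross-validation on macro-F1
(5 inner / 10 outer folds), and attribute predictions to substructure
features with exact tree-ensemble Shapley values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import spearmanr
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import classification_report, f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from ._treeshap import tree_shap_values

__all__ = [
    "load_catalog",
    "substructure_fingerprint",
    "feature_matrix",
    "prune_features",
    "stratified_split",
    "smote_oversample",
    "nested_cv_train",
    "shap_explain",
    "ModelEvaluation",
    "unreliable_classes",
]


class CatalogError(ValueError):
    pass


class FeatureError(ValueError):
    pass


def load_catalog(path: Optional[str | Path] = None) -> dict[str, Chem.Mol]:
    """Load a name<TAB>SMARTS[<TAB>example] catalog into compiled patterns.

    Defaults to the shipped functional-group catalog.  Malformed entries
    raise at load time, never at match time.
    """
    if path is None:
        source = resources.files("enrspace.data").joinpath("substructure_keys.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    catalog: dict[str, Chem.Mol] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise CatalogError(f"line {lineno}: expected name<TAB>SMARTS")
        name, smarts = parts[0], parts[1]
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise CatalogError(f"line {lineno}: invalid SMARTS for {name!r}: {smarts!r}")
        if name in catalog:
            raise CatalogError(f"line {lineno}: duplicate key {name!r}")
        catalog[name] = patt
    if not catalog:
        raise CatalogError("empty catalog")
    return catalog


def substructure_fingerprint(mol_or_smiles, catalog: dict[str, Chem.Mol]) -> dict[str, int]:
    """Count of distinct matches per catalog key."""
    mol = mol_or_smiles
    if not isinstance(mol, Chem.Mol):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise FeatureError(f"unparsable SMILES: {mol_or_smiles!r}")
    return {
        name: len(mol.GetSubstructMatches(patt, uniquify=True))
        for name, patt in catalog.items()
    }


def feature_matrix(
    records, catalog: Optional[dict[str, Chem.Mol]] = None
) -> pd.DataFrame:
    """Substructure-count matrix with id, enzyme and activity columns."""
    if catalog is None:
        catalog = load_catalog()
    rows = []
    for r in records:
        counts = substructure_fingerprint(r.smiles or r.smiles_raw, catalog)
        counts.update(id=r.id, enzyme=r.enzyme, activity_class=r.activity_class)
        rows.append(counts)
    df = pd.DataFrame(rows)
    meta = ["id", "enzyme", "activity_class"]
    return df[meta + [c for c in df.columns if c not in meta]]


def prune_features(
    train: pd.DataFrame, rho: float = 0.7, feature_cols: Optional[list[str]] = None
) -> tuple[pd.DataFrame, list[str]]:
    """Remove invariant then highly correlated columns (train rows only).

    Columns are scanned in descending-variance order (ties by name); a
    column with |Spearman rho| > ``rho`` against any already-kept column is
    dropped.  Returns the reduced frame and the kept-column list, to be
    applied unchanged to test data.
    """
    if feature_cols is None:
        feature_cols = [c for c in train.columns if train[c].dtype.kind in "if"]
    X = train[feature_cols]
    variances = X.var(axis=0)
    candidates = [c for c in feature_cols if variances[c] > 0]
    if not candidates:
        raise FeatureError("all feature columns are invariant")
    order = sorted(candidates, key=lambda c: (-variances[c], c))
    kept: list[str] = []
    if len(order) > 1:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corr, _ = spearmanr(X[order].values)
        corr = np.atleast_2d(corr)
    else:
        corr = np.ones((1, 1))
    pos = {c: i for i, c in enumerate(order)}
    for col in order:
        if all(abs(corr[pos[col], pos[k]]) <= rho for k in kept):
            kept.append(col)
    kept = sorted(kept, key=feature_cols.index)
    other = [c for c in train.columns if c not in feature_cols]
    return train[other + kept], kept


def stratified_split(
    table: pd.DataFrame,
    ratio: float = 0.7,
    seed: int = 0,
    strata_cols: Sequence[str] = ("enzyme", "activity_class"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint stratified train/test split (train fraction = ``ratio``)."""
    strata = table[list(strata_cols)].astype(str).agg("|".join, axis=1)
    small = strata.value_counts()
    bad = small[small < 2]
    if len(bad):
        raise FeatureError(f"strata too small to split: {dict(bad)}")
    train, test = train_test_split(
        table, train_size=ratio, random_state=seed, stratify=strata
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    target: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic Minority Oversampling Technique.

    Every synthetic sample is x_i + u (x_nn - x_i) with u ~ U(0,1) and x_nn
    one of the k nearest same-class neighbours, so it lies on the segment
    between two minority points.  Classes are raised to ``target`` counts
    (default: the majority class size).  Returns (X_out, y_out,
    synthetic_mask).  Training data only — never resample a test set.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if target is None:
        majority = counts.max()
        target = {c: majority for c in classes}
    new_X, new_y = [], []
    for cls in classes:
        need = target.get(cls, 0) - int((y == cls).sum())
        if need <= 0:
            continue
        Xc = X[y == cls]
        if len(Xc) <= k:
            raise FeatureError(
                f"class {cls!r} has {len(Xc)} samples <= k={k}; use a smaller k"
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(1, k + 1, size=need)  # skip self at position 0
        u = rng.random(need)
        neigh = Xc[idx[base, pick]]
        new_X.append(Xc[base] + u[:, None] * (neigh - Xc[base]))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    if not new_X:
        return X, y, np.zeros(len(y), dtype=bool)
    X_out = np.vstack([X] + new_X)
    y_out = np.concatenate([y] + new_y)
    mask = np.concatenate([np.zeros(len(y), dtype=bool), np.ones(len(X_out) - len(y), dtype=bool)])
    return X_out, y_out, mask


@dataclass
class ModelEvaluation:
    per_class: dict  # class -> {precision, recall, f1, support}
    macro_f1: float
    provenance: str  # "train" | "test" | "outer_cv"
    chosen_params: dict = field(default_factory=dict)
    cv_fold_scores: list[float] = field(default_factory=list)


DEFAULT_GRID = {"n_estimators": [100], "max_depth": [None, 8]}


def nested_cv_train(
    X: np.ndarray,
    y: np.ndarray,
    estimator=None,
    param_grid: Optional[dict] = None,
    seed: int = 0,
    inner_splits: int = 5,
    outer_splits: int = 10,
):
    """Nested cross-validation model selection on macro-F1.

    Inner k-fold grid search per outer fold gives an unbiased outer
    estimate; the final model is refit on all rows with the best
    hyperparameters.  Degenerate folds (a single class present) are skipped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if estimator is None:
        estimator = RandomForestClassifier(random_state=seed)
    if param_grid is None:
        param_grid = dict(DEFAULT_GRID)
    inner = StratifiedKFold(n_splits=inner_splits, shuffle=True, random_state=seed)
    outer = StratifiedKFold(n_splits=outer_splits, shuffle=True, random_state=seed)
    fold_scores: list[float] = []
    for tr, te in outer.split(X, y):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            warnings.warn("skipping degenerate outer fold with a single class")
            continue
        gs = GridSearchCV(clone(estimator), param_grid, scoring="f1_macro", cv=inner)
        gs.fit(X[tr], y[tr])
        fold_scores.append(float(f1_score(y[te], gs.predict(X[te]), average="macro")))
    final = GridSearchCV(clone(estimator), param_grid, scoring="f1_macro", cv=inner)
    final.fit(X, y)
    model = final.best_estimator_
    evaluation = evaluate(model, X, y, provenance="train")
    evaluation.chosen_params = dict(final.best_params_)
    evaluation.cv_fold_scores = fold_scores
    return model, evaluation


def evaluate(model, X, y, provenance: str = "test") -> ModelEvaluation:
    """Per-class precision/recall/F1 and macro-F1 for fitted ``model``."""
    y_pred = model.predict(np.asarray(X, dtype=float))
    report = classification_report(y, y_pred, output_dict=True, zero_division=0)
    per_class = {
        k: {"precision": v["precision"], "recall": v["recall"],
            "f1": v["f1-score"], "support": v["support"]}
        for k, v in report.items()
        if isinstance(v, dict) and k not in ("macro avg", "weighted avg")
    }
    return ModelEvaluation(
        per_class=per_class,
        macro_f1=float(report["macro avg"]["f1-score"]),
        provenance=provenance,
    )


def unreliable_classes(evaluation: ModelEvaluation, floor: float = 0.5) -> list[str]:
    """Classes whose test precision or recall falls below ``floor``.

    Mirrors the practice of excluding a tiny dataset (e.g. 15 molecules)
    from attribution analysis when its model is not trustworthy.
    """
    return sorted(
        cls
        for cls, m in evaluation.per_class.items()
        if m["precision"] < floor or m["recall"] < floor
    )


def shap_explain(
    model, X, feature_names: Optional[Sequence[str]] = None, class_index: int = 1
) -> dict:
    """Per-sample, per-feature Shapley attributions plus a ranked summary.

    Only exact tree models are supported (DecisionTree / RandomForest /
    ExtraTrees and other sklearn ensembles exposing ``estimators_``).
    Attributions satisfy local accuracy: per sample they sum to the model
    output minus the expected output.
    """
    X = np.asarray(X, dtype=float)
    phi, base = tree_shap_values(model, X, class_index=class_index)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    mean_abs = np.abs(phi).mean(axis=0)
    mean_signed = phi.mean(axis=0)
    order = np.argsort(-mean_abs)
    summary = pd.DataFrame(
        {
            "feature": [feature_names[i] for i in order],
            "mean_abs_attribution": mean_abs[order],
            "mean_attribution": mean_signed[order],
        }
    )
    return {
        "attributions": phi,
        "expected_value": base,
        "feature_names": list(feature_names),
        "summary": summary,
    }
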