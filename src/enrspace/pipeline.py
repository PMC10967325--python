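"""End-to-end profiling pipeline with machine-readable reports.

Stages: curation -> descriptor/filter profiling -> group statistics ->
scaffold diversity -> Butina clustering -> matched-pair / activity-cliff
mining -> substructure feature importance.  Every stage writes CSV/JSON
artifacts into the output directory and contributes headline counts to a
single summary JSON; identical config + seed reproduces the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from . import complexity as cx
from . import curation as cur
from . import descriptors as dsc
from . import features as ft
from . import mmp as mmp_mod
from . import scaffolds as scf
from . import similarity as sim
from . import stats as st

log = logging.getLogger("enrspace")

__all__ = ["PipelineConfig", "run"]


@dataclass
class PipelineConfig:
    input_path: Optional[str] = None
    input_format: str = "csv"  # csv | sdf
    output_dir: str = "enrspace_out"
    activity_threshold: float = 5.5
    butina_threshold: float = 0.75
    mmp: mmp_mod.MMPConfig = field(default_factory=mmp_mod.MMPConfig)
    fingerprint_kind: str = "ECFP4"
    ml_ratio: float = 0.7
    ml_rho: float = 0.7
    ml_smote_k: int = 5
    ml_inner_splits: int = 5
    ml_outer_splits: int = 10
    ml_target: str = "activity_class"  # binary activity; per-enzyme grouping
    reliability_floor: float = 0.5
    include_tsne: bool = False
    tsne_perplexity: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.butina_threshold <= 1:
            raise ValueError("butina_threshold must be in (0, 1]")
        if not 0 < self.ml_ratio < 1:
            raise ValueError("ml_ratio must be in (0, 1)")


def run(config: PipelineConfig, records: Optional[list] = None) -> dict:
    """Run every stage; return the report bundle (also written to disk)."""
    config.validate()
    t0 = time.time()
    if records is None:
        if config.input_path is None:
            raise FileNotFoundError("no input: provide input_path or records")
        path = Path(config.input_path)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        records = (
            cur.read_sdf(path) if config.input_format == "sdf" else cur.read_csv(path)
        )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": config.seed}

    # --- curation ---------------------------------------------------------
    curated, clog = cur.curate(records, threshold=config.activity_threshold)
    frame = cur.curated_frame(curated)
    frame.to_csv(out / "curated.csv", index=False)
    by_enzyme = frame.groupby("enzyme").size().to_dict()
    summary["curation"] = {
        "n_input": clog.n_input,
        "n_curated": clog.n_output,
        "n_imputed": clog.n_imputed,
        "n_duplicates_removed": clog.n_duplicates_removed,
        "dropped": clog.dropped,
        "per_enzyme": by_enzyme,
        "n_active": int((frame["activity_class"] == "active").sum()),
        "n_inactive": int((frame["activity_class"] == "inactive").sum()),
    }
    log.info("curated %d -> %d records", clog.n_input, clog.n_output)

    # --- descriptors and filters -----------------------------------------
    mols = {r.id: Chem.MolFromSmiles(r.smiles) for r in curated}
    desc_rows = []
    filt_rows = []
    for r in curated:
        d = dsc.compute_descriptors(mols[r.id])
        d["id"] = r.id
        desc_rows.append(d)
        filt_rows.append(
            {
                "id": r.id,
                "lipinski_violations": dsc.lipinski_violations(d),
                "n_pains": len(dsc.pains_hits(mols[r.id])),
                "n_brenk": len(dsc.brenk_hits(mols[r.id])),
            }
        )
    desc_df = pd.DataFrame(desc_rows).set_index("id")
    filt_df = pd.DataFrame(filt_rows).set_index("id")
    desc_df.to_csv(out / "descriptors.csv")
    filt_df.to_csv(out / "filter_report.csv")
    summary["filters"] = {
        "pct_lipinski_clean": float(100 * (filt_df["lipinski_violations"] == 0).mean()),
        "pct_pains": float(100 * (filt_df["n_pains"] > 0).mean()),
        "pct_brenk": float(100 * (filt_df["n_brenk"] > 0).mean()),
    }

    # --- group statistics -------------------------------------------------
    stat_table = frame.set_index("id").join(desc_df)
    stats_df = st.descriptor_comparison_table(stat_table)
    stats_df.to_csv(out / "group_statistics.csv", index=False)
    summary["statistics"] = {
        "n_tests": int(len(stats_df)),
        "n_significant": int(stats_df["reject"].sum()) if len(stats_df) else 0,
    }

    # --- scaffold diversity ----------------------------------------------
    scaffold_of = {r.id: scf.murcko_scaffold(r.smiles) for r in curated}
    diversity = {}
    chemo_rows = []
    for enzyme, sub in frame.groupby("enzyme"):
        entry = {}
        for subset in ("all", "active", "inactive"):
            sel = sub if subset == "all" else sub[sub["activity_class"] == subset]
            if not len(sel):
                continue
            table = scf.chemotype_stats([scaffold_of[i] for i in sel["id"]])
            metrics = {
                "N": table.N, "M": table.M, "N_sing": table.N_sing,
                "N_over_M": table.n_over_m,
            }
            try:
                curve = scf.csr_curve(table)
                se, sse = scf.shannon_entropy(table, n=min(20, max(2, table.N)))
                metrics.update(AUC=curve.auc, F50=curve.f50, SE=se, SSE=sse)
            except scf.ScaffoldError:
                pass
            entry[subset] = metrics
            for smi, cnt in sorted(table.counts.items()):
                chemo_rows.append(
                    {"enzyme": enzyme, "subset": subset, "scaffold": smi,
                     "count": cnt, "is_singleton": cnt == 1}
                )
        diversity[enzyme] = entry
    pd.DataFrame(chemo_rows).to_csv(out / "chemotypes.csv", index=False)
    with open(out / "diversity.json", "w") as fh:
        json.dump(diversity, fh, indent=2)
    summary["diversity"] = {
        e: {"N": v["all"]["N"], "AUC": v["all"].get("AUC"), "F50": v["all"].get("F50")}
        for e, v in diversity.items()
    }

    # --- similarity + clustering (per enzyme) -----------------------------
    cluster_rows = []
    cluster_summary = {}
    for enzyme, sub in frame.groupby("enzyme"):
        ids = sorted(sub["id"])  # id-sorted input: stable centroid tie-breaks
        fps = [sim.fingerprint(mols[i], config.fingerprint_kind) for i in ids]
        cs = sim.butina_cluster(fps, threshold=config.butina_threshold)
        pic50 = [float(frame.set_index("id").loc[i, "pic50"]) for i in ids]
        activity = [str(frame.set_index("id").loc[i, "activity_class"]) for i in ids]
        emols = [mols[i] for i in ids]
        for ci, cluster in enumerate(cs.clusters):
            sim.cluster_profile(cluster, fps, emols, pic50, activity)
            for m in cluster.members:
                cluster_rows.append(
                    {"enzyme": enzyme, "cluster": ci, "id": ids[m],
                     "is_centroid": m == cluster.centroid}
                )
        cluster_summary[enzyme] = {
            "n_clusters": cs.n_clusters,
            "n_compounds": len(ids),
            "n_singletons": sum(1 for c in cs.clusters if c.n_cmp == 1),
        }
    pd.DataFrame(cluster_rows).to_csv(out / "clusters.csv", index=False)
    summary["clustering"] = cluster_summary

    if config.include_tsne:
        ids = sorted(frame["id"])
        fps = [sim.fingerprint(mols[i], config.fingerprint_kind) for i in ids]
        if len(fps) > config.tsne_perplexity * 3:
            coords = sim.tsne_embed(fps, config.tsne_perplexity, seed=config.seed)
            pd.DataFrame(
                {"id": ids, "x": coords[:, 0], "y": coords[:, 1]}
            ).to_csv(out / "tsne.csv", index=False)

    # --- complexity -------------------------------------------------------
    cxs = cx.complexity_report(stat_table.reset_index())
    cxs.group_stats.to_csv(out / "complexity.csv", index=False)
    summary["complexity"] = {
        "correlations": {
            k: (None if v is None else {"r": v[0], "p": v[1]})
            for k, v in cxs.correlations.items()
        }
    }

    # --- matched pairs / cliffs (per enzyme) ------------------------------
    mmp_cfg = dataclasses.replace(
        config.mmp, activity_threshold=config.activity_threshold
    )
    mmp_summary = {}
    pair_rows = []
    total_pairs = total_cliffs = 0
    for enzyme, sub in frame.groupby("enzyme"):
        sub_records = [r for r in curated if r.enzyme == enzyme]
        result = mmp_mod.run_mmp_analysis(sub_records, mmp_cfg)
        for p in result["pairs"]:
            pair_rows.append(
                {"enzyme": enzyme, "id_a": p.id_a, "id_b": p.id_b, "context": p.key,
                 "transformation": p.transformation, "tanimoto": p.similarity,
                 "heavy_atom_diff": p.heavy_atom_diff, "delta_pic50": p.delta_pic50,
                 "category": p.category}
            )
        n_cliffs = result["category_counts"]["activity_cliff"]
        total_pairs += result["n_pairs"]
        total_cliffs += n_cliffs
        mmp_summary[enzyme] = {
            "n_pairs": result["n_pairs"],
            "n_transformations": result["n_transformations"],
            "n_passing_transformations": result["n_passing_transformations"],
            "category_counts": result["category_counts"],
            "n_unique_cliff_fragments": result["cliff_fragments"]["n_unique"],
            "median_fragment_slogp": result["cliff_fragments"]["median_slogp"],
        }
    pd.DataFrame(pair_rows).to_csv(out / "matched_pairs.csv", index=False)
    summary["mmp"] = {
        "per_enzyme": mmp_summary,
        "n_pairs_total": total_pairs,
        "n_cliffs_total": total_cliffs,
    }

    # --- feature importance ----------------------------------------------
    matrix = ft.feature_matrix(curated)
    try:
        train, test = ft.stratified_split(matrix, ratio=config.ml_ratio, seed=config.seed)
    except ft.FeatureError as exc:
        log.warning("ML stage skipped: %s", exc)
        summary["ml"] = {"skipped": str(exc)}
        train = None
    if train is not None:
        pruned_train, kept = ft.prune_features(
            train, rho=config.ml_rho,
            feature_cols=[c for c in matrix.columns if c not in ("id", "enzyme", "activity_class")],
        )
        y_train = train["activity_class"].values
        X_train = pruned_train[kept].values.astype(float)
        counts = pd.Series(y_train).value_counts()
        if counts.min() > config.ml_smote_k and len(counts) > 1:
            X_res, y_res, _ = ft.smote_oversample(
                X_train, y_train, k=config.ml_smote_k, seed=config.seed
            )
        else:
            X_res, y_res = X_train, y_train
        model, train_eval = ft.nested_cv_train(
            X_res, y_res, seed=config.seed,
            inner_splits=config.ml_inner_splits, outer_splits=config.ml_outer_splits,
        )
        X_test = test[kept].values.astype(float)
        test_eval = ft.evaluate(model, X_test, test["activity_class"].values)
        explain = ft.shap_explain(model, X_test, feature_names=kept)
        explain["summary"].to_csv(out / "attribution_summary.csv", index=False)
        summary["ml"] = {
            "n_features_initial": int(matrix.shape[1] - 3),
            "n_features_kept": len(kept),
            "macro_f1_outer_cv": float(np.mean(train_eval.cv_fold_scores))
            if train_eval.cv_fold_scores else None,
            "macro_f1_train": train_eval.macro_f1,
            "macro_f1_test": test_eval.macro_f1,
            "chosen_params": train_eval.chosen_params,
            "unreliable_classes": ft.unreliable_classes(
                test_eval, floor=config.reliability_floor
            ),
            "top_features": explain["summary"]["feature"].head(10).tolist(),
        }
        with open(out / "model_evaluation.json", "w") as fh:
            json.dump(
                {"train": train_eval.per_class, "test": test_eval.per_class,
                 "macro_f1_train": train_eval.macro_f1,
                 "macro_f1_test": test_eval.macro_f1},
                fh, indent=2,
            )

    log.info("pipeline finished in %.1f s", time.time() - t0)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
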