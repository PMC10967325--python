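"""Fingerprints, Tanimoto similarity, t-SNE embedding, and Butina clustering.

Two fingerprint flavours are supported: 166-bit MACCS structural keys and
2048-bit radius-2 Morgan circular fingerprints (ECFP4).  Chemical-space
structure is summarized by intra-/inter-group Tanimoto statistics and CDFs,
a 2-D t-SNE embedding (visualization only), and Taylor-Butina
sphere-exclusion clustering at a similarity threshold of 0.75, with each
cluster profiled by intra-cluster similarity, activity statistics and the
maximum common substructure (ring atoms matching ring atoms only).
"""

from __future__ import annotations

import statistics as pystats
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFMCS, rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "similarity_summary",
    "tsne_embed",
    "butina_cluster",
    "cluster_profile",
    "ClusterSet",
    "Cluster",
]

BUTINA_THRESHOLD = 0.75

_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class SimilarityError(ValueError):
    pass


@dataclass
class Fingerprint:
    kind: str  # "MACCS" | "ECFP4"
    bits: frozenset[int]
    length: int

    def to_bitvect(self):
        from rdkit.DataStructs import ExplicitBitVect

        bv = ExplicitBitVect(self.length)
        for b in self.bits:
            bv.SetBit(b)
        return bv


def fingerprint(mol_or_smiles, kind: str = "ECFP4") -> Fingerprint:
    """MACCS (166 bits) or ECFP4 (Morgan radius 2, 2048 bits)."""
    mol = mol_or_smiles
    if not isinstance(mol, Chem.Mol):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise SimilarityError(f"unparsable SMILES: {mol_or_smiles!r}")
    if kind == "ECFP4":
        bv = _morgan.GetFingerprint(mol)
        length = 2048
    elif kind == "MACCS":
        bv = MACCSkeys.GenMACCSKeys(mol)
        length = bv.GetNumBits()
    else:
        raise SimilarityError(f"unknown fingerprint kind {kind!r}")
    return Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), length=length)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; 1.0 when both fingerprints are empty."""
    if a.kind != b.kind:
        raise SimilarityError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def similarity_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense symmetric pairwise Tanimoto matrix."""
    bvs = [fp.to_bitvect() for fp in fps]
    n = len(bvs)
    mat = np.ones((n, n))
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(bvs[i], bvs[:i])
        mat[i, :i] = row
        mat[:i, i] = row
    return mat


def _pairwise_values(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def similarity_summary(groups: dict[str, Sequence[Fingerprint]]) -> dict:
    """Mean intra-/inter-group Tanimoto matrix plus per-group stats and CDFs.

    Intra-group similarity averages all unordered distinct pairs; singleton
    groups get ``None`` (flagged undefined).  Inter-group averages all cross
    pairs.  CDFs are returned as sorted similarity values per group.
    """
    if not groups:
        raise SimilarityError("at least one group required")
    names = sorted(groups)
    matrix = {}
    stats = {}
    cdfs = {}
    for i, ga in enumerate(names):
        fa = list(groups[ga])
        for gb in names[i:]:
            fb = list(groups[gb])
            if ga == gb:
                if len(fa) < 2:
                    matrix[(ga, gb)] = None
                    continue
                vals = _pairwise_values(similarity_matrix(fa))
            else:
                bvs_a = [f.to_bitvect() for f in fa]
                bvs_b = [f.to_bitvect() for f in fb]
                vals = np.array(
                    [s for bv in bvs_a for s in DataStructs.BulkTanimotoSimilarity(bv, bvs_b)]
                )
            matrix[(ga, gb)] = matrix[(gb, ga)] = float(vals.mean())
            if ga == gb:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                stats[ga] = {
                    "mean": float(vals.mean()),
                    "median": float(med),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "q1": float(q1),
                    "q3": float(q3),
                    "n_pairs": int(vals.size),
                }
                cdfs[ga] = np.sort(vals)
    return {"matrix": matrix, "group_stats": stats, "cdf": cdfs}


def tsne_embed(
    fps: Sequence[Fingerprint], perplexity: float = 30.0, seed: int = 0
) -> np.ndarray:
    """2-D t-SNE coordinates (visualization only, never used downstream)."""
    n = len(fps)
    if n <= perplexity * 3:
        raise SimilarityError(
            f"t-SNE needs n > 3*perplexity; got n={n}, perplexity={perplexity}"
        )
    from sklearn.manifold import TSNE

    X = np.zeros((n, fps[0].length), dtype=np.float32)
    for i, fp in enumerate(fps):
        X[i, list(fp.bits)] = 1.0
    return TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(X)


# ---------------------------------------------------------------------------
# Taylor-Butina sphere-exclusion clustering


@dataclass
class Cluster:
    centroid: int  # index into the input sequence
    members: list[int]  # includes centroid
    int_sim: Optional[float] = None  # median pairwise Tanimoto; None = singleton flag
    pct_actives: Optional[float] = None
    q3_pic50: Optional[float] = None
    max_pic50: Optional[float] = None
    n_cmp: int = 0
    mcs_smarts: Optional[str] = None
    mcs_timed_out: bool = False


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def butina_cluster(
    fps: Sequence[Fingerprint], threshold: float = BUTINA_THRESHOLD
) -> ClusterSet:
    """Taylor-Butina clustering on a similarity threshold.

    Neighbours are pairs with Tanimoto >= threshold.  The unassigned
    molecule with the most unassigned neighbours (ties: smallest input
    index) becomes the next centroid and claims its unassigned neighbours;
    leftovers end as singletons.  The result partitions the input.
    """
    n = len(fps)
    if n == 0:
        raise SimilarityError("cannot cluster an empty set")
    mat = similarity_matrix(fps)
    neighbors = [set(np.nonzero(mat[i] >= threshold)[0]) - {i} for i in range(n)]
    unassigned = set(range(n))
    clusters: list[Cluster] = []
    while unassigned:
        best = min(unassigned, key=lambda i: (-len(neighbors[i] & unassigned), i))
        members = sorted((neighbors[best] & unassigned) | {best})
        clusters.append(Cluster(centroid=best, members=members, n_cmp=len(members)))
        unassigned -= set(members)
    return ClusterSet(clusters=clusters, threshold=threshold)


def cluster_profile(
    cluster: Cluster,
    fps: Sequence[Fingerprint],
    mols: Sequence[Chem.Mol],
    pic50: Sequence[float],
    activity: Sequence[str],
    active_label: str = "active",
    mcs_timeout: int = 10,
) -> Cluster:
    """Fill in IntSim, activity statistics and the ring-constrained MCS."""
    idx = cluster.members
    if not idx:
        raise SimilarityError("empty cluster")
    if len(idx) == 1:
        cluster.int_sim = None  # undefined for singletons (flag)
    else:
        sims = [tanimoto(fps[i], fps[j]) for k, i in enumerate(idx) for j in idx[k + 1 :]]
        cluster.int_sim = float(pystats.median(sims))
    vals = [pic50[i] for i in idx]
    cluster.pct_actives = 100.0 * sum(activity[i] == active_label for i in idx) / len(idx)
    cluster.q3_pic50 = float(np.percentile(vals, 75))
    cluster.max_pic50 = float(max(vals))
    if len(idx) >= 2:
        res = rdFMCS.FindMCS(
            [mols[i] for i in idx],
            ringMatchesRingOnly=True,
            timeout=mcs_timeout,
        )
        cluster.mcs_smarts = res.smartsString or None
        cluster.mcs_timed_out = bool(res.canceled)
    return cluster
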