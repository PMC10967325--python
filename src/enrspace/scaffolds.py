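"""Bemis-Murcko chemotype extraction and scaffold-diversity metrics.

A chemotype is the Bemis-Murcko scaffold: ring systems plus the linkers
connecting them, with all substituents removed (atom types retained — no
generic frameworks).  Diversity of a compound set is summarized by

* N unique chemotypes, M molecules, N_sing singleton chemotypes and the
  ratios N/M, N_sing/N, N_sing/M;
* the cyclic-system-retrieval (CSR) curve: cumulative fraction of compounds
  recovered vs fraction of chemotypes, chemotypes sorted by frequency;
* AUC of the CSR curve (0.5 = perfectly even, -> 1 under concentration)
  and F50, the chemotype fraction covering half the compounds;
* scaled Shannon entropy (SSE) over the n most populated chemotypes
  (1 = maximally even, 0 = single dominant chemotype).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

__all__ = [
    "NO_RING_SENTINEL",
    "murcko_scaffold",
    "ChemotypeTable",
    "chemotype_stats",
    "CSRCurve",
    "csr_curve",
    "shannon_entropy",
]

#: Chemotype assigned to acyclic molecules (excluded from CSR curves).
NO_RING_SENTINEL = ""


class ScaffoldError(ValueError):
    pass


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; '' for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ScaffoldError(f"unparsable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return NO_RING_SENTINEL
    return Chem.MolToSmiles(scaffold)


@dataclass
class ChemotypeTable:
    counts: dict[str, int]  # scaffold SMILES -> compound count
    M: int
    N: int
    N_sing: int

    @property
    def n_over_m(self) -> float:
        return self.N / self.M

    @property
    def nsing_over_n(self) -> float:
        return self.N_sing / self.N

    @property
    def nsing_over_m(self) -> float:
        return self.N_sing / self.M


def chemotype_stats(scaffolds: list[str]) -> ChemotypeTable:
    """Exact chemotype counts for a list of per-molecule scaffold SMILES."""
    if not scaffolds:
        raise ScaffoldError("empty subset: no chemotype statistics")
    counts = dict(Counter(scaffolds))
    return ChemotypeTable(
        counts=counts,
        M=len(scaffolds),
        N=len(counts),
        N_sing=sum(1 for c in counts.values() if c == 1),
    )


@dataclass
class CSRCurve:
    x: np.ndarray  # fraction of chemotypes, (0, 1/N, ..., 1)
    y: np.ndarray  # cumulative compound fraction, starts at 0, ends at 1
    auc: float
    f50: float


def csr_curve(table: ChemotypeTable, include_no_ring: bool = False) -> CSRCurve:
    """Cyclic-system-retrieval curve with trapezoidal AUC and F50.

    Counts are sorted descending (ties broken by scaffold SMILES) and the
    origin point is prepended, so a perfectly uniform distribution has
    AUC exactly 0.5.  Tables with fewer than two chemotypes yield the
    degenerate curve with F50 = 1.0 by convention.
    """
    counts = dict(table.counts)
    if not include_no_ring:
        counts.pop(NO_RING_SENTINEL, None)
    if not counts:
        raise ScaffoldError("no ring-containing chemotypes for a CSR curve")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ordered)
    total = sum(c for _, c in ordered)
    y = np.concatenate([[0.0], np.cumsum([c / total for _, c in ordered])])
    y[-1] = 1.0
    x = np.arange(n + 1) / n
    auc = float(np.trapezoid(y, x))
    if n < 2:
        f50 = 1.0
    else:
        f50 = float(x[np.argmax(y >= 0.5)])
    return CSRCurve(x=x, y=y, auc=auc, f50=f50)


def shannon_entropy(table: ChemotypeTable, n: int = 20) -> tuple[float, float]:
    """(SE, SSE) over the n most populated chemotypes.

    SE = -sum p_i log2 p_i with p_i normalized over the selected chemotypes;
    SSE = SE / log2(n) in [0, 1].  Chemotypes beyond the table's N
    contribute zero counts, so a single dominant chemotype gives SSE = 0
    and n equally populated chemotypes give SSE = 1.
    """
    if n < 2:
        raise ScaffoldError("entropy window n must be >= 2")
    if not table.counts:
        raise ScaffoldError("empty chemotype table")
    top = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    c = np.array([cnt for _, cnt in top], dtype=float)
    p = c / c.sum()
    se = float(-(p * np.log2(p, where=p > 0, out=np.zeros_like(p))).sum())
    return se, se / float(np.log2(n))
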