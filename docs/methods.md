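# Methods

`enrspace` profiles the chemical space of enoyl-ACP reductase (ENR)
inhibitors — datasets of molecules annotated with an IC50 against one of
the four enzymes InhA, FabI, FabK or FabV — through a fixed sequence of
stages.  This note records the models and conventions behind each stage,
the defaults and why they hold, and what the synthetic benchmark does and
does not demonstrate.

## Curation

Raw records are SMILES + IC50 + enzyme label.  Standardization keeps the
largest covalent fragment (salt/solvent stripping), neutralizes charges
where possible and preserves explicit stereochemistry; the operation is
idempotent.  Records whose IC50 is missing, or flagged qualitative-inactive
(reported enzyme activity > 80 % or inhibition < 20 %), are imputed at
IC50 = 100 µM exactly (pIC50 4.0).  Activities convert as
pIC50 = −log10(IC50 / 1 M).  Duplicates share a (canonical desalted SMILES,
enzyme) key and the most potent measurement survives; exact-potency ties
resolve to the lexicographically smallest record id so output is
order-independent.  A compound is *active* iff pIC50 ≥ 5.5 — the threshold
sits midway in the 5–6 range conventional for this enzyme family, and the
≥ (rather than >) convention is applied at the boundary.  Stereoisomers
with distinct stereo-SMILES are distinct compounds.  Unparsable SMILES and
unknown enzyme labels are dropped with a per-reason count in the curation
log.

## Descriptor panel and filters

A fixed panel of 39 descriptors is computed per molecule, most from RDKit
(SlogP, TPSA, molecular weight, H-bond donors/acceptors, ring counts,
BertzCT, kappa shape indices, …).  Three members are implemented in-package
from their published definitions:

* **apol** — sum of atomic static dipole polarizabilities (10⁻²⁴ cm³) over
  all atoms including hydrogens;
* **fragCpx** — Nilakantan fragment complexity |B² − A² + A| + H/100
  (B bonds, A heavy atoms, H heteroatoms);
* **LogS** — an ESOL-style aqueous solubility estimate
  (0.16 − 0.63 logP − 0.0062 MW + 0.066 RB − 0.74 AP).  This is a different
  estimator from Filter-it's logS; values are comparable in trend, not in
  magnitude, and nothing downstream depends on its dialect.

Descriptors are evaluated on the canonical structure (inputs are reparsed
from canonical SMILES first) so float summation order cannot make two
representations of one molecule disagree.  A failed estimator is recorded
as missing, never as silent zero.

Lipinski violations count strict excess only — MW > 500, N+O−H donors > 5,
N+O acceptors > 10, SlogP > 5 — so boundary values comply; donor/acceptor
counts use the original OH/NH and N/O conventions.  PAINS and Brenk
substructure screens run through RDKit's curated `FilterCatalog`; the RDKit
version is pinned by the environment, which protects the counts from
catalog drift the same way a vendored SMARTS file would.

## Group statistics

Descriptor distributions in such datasets are heavy-tailed, so all
between-group comparisons are non-parametric: Kruskal–Wallis (tie-corrected
H, χ² p-value, k−1 df) screens the four enzyme datasets, Mann–Whitney U
compares actives vs inactives within each enzyme (exact null when both
groups have ≤ 8 observations and no ties, normal approximation with tie
correction otherwise), and Holm–Bonferroni (step-down, α = 0.05) controls
the family-wise error over all descriptor × comparison tests in one
analysis table — the family is configurable because other groupings are
defensible.  Kolmogorov–Smirnov (against a fitted normal) and
D'Agostino–Pearson normality tests are computed for reporting only; the
comparison path never branches on them.  The default comparison panel is
BertzCT, fragCpx, LogS, apol, RotBFrac, SlogP, TPSA, AMW.

## Scaffold diversity

Chemotypes are Bemis–Murcko scaffolds (rings plus connecting linkers,
substituents removed) with atom types retained — generic carbon-skeleton
frameworks are deliberately not used.  Acyclic molecules share one
"no-ring" chemotype which is excluded from retrieval curves.  The
cyclic-system-retrieval (CSR) curve plots cumulative compound fraction
against chemotype fraction with chemotypes sorted by descending count
(ties by scaffold SMILES); the origin is prepended so a perfectly uniform
distribution has trapezoidal AUC exactly 0.5.  F50 is the smallest
chemotype fraction covering half the compounds; tables with fewer than two
chemotypes get F50 = 1.0 by convention.  Scaled Shannon entropy over the
n most populated chemotypes (default n = 20) is SE/log₂(n) ∈ [0, 1].

## Similarity and clustering

Fingerprints are 166-bit MACCS keys or 2048-bit radius-2 Morgan circular
fingerprints (ECFP4); Tanimoto similarity |A∩B|/|A∪B| is used throughout
(1.0 when both sets are empty).  Taylor–Butina sphere-exclusion clustering
treats pairs with similarity ≥ 0.75 as neighbours; the unassigned molecule
with the most unassigned neighbours becomes the next centroid (ties:
smallest input index, with input sorted by molecule id, making partitions
reproducible).  Each cluster is profiled by the median pairwise Tanimoto
(undefined and flagged for singletons), % actives, Q3 and max of pIC50, and
the maximum common substructure computed with ring atoms constrained to
match ring atoms, a 10 s timeout and a partial-result flag.  t-SNE
embeddings of fingerprint space are provided for visualization only and
feed nothing downstream.  Clustering runs per enzyme by default (pooled
optional).

## Matched molecular pairs and activity cliffs

Fragmentation deletes acyclic single bonds between two non-hydrogen atoms —
single cuts and unordered combinations up to `max_cuts` (default 2;
1–3 supported).  Explicit hydrogens are removed and stereochemistry ignored
first.  Each cut set yields one key/value record: the *value* (variable
fragment) carries every numbered attachment point and the *key* is the
remaining context.  For a single cut the smaller fragment is the variable
part (ties by SMILES order); this keeps one record per cut — the
"transformation" then always describes the localized change, and larger
rearrangements such as core swaps are still captured by the multi-cut
records whose middle fragment is the core.  Attachment maps are renumbered
by the value fragment's canonical atom ranks before writing SMILES, so
transformation identity is representation-independent, and every record
reassembles (`molzip`) to its parent's canonical SMILES.

Two molecules sharing a key with different values form a candidate pair,
kept when ECFP4 Tanimoto > 0.56 (strict, as printed) and heavy-atom count
difference ≤ 10, with transformations observed in < 4 distinct pairs
discarded.  Direction is canonical (lexicographically smaller value first,
ΔpIC50 signed accordingly) and each unordered pair appears once per
distinct transformation.

The four-way taxonomy uses the literal concentration rule with
d = |IC50ₐ − IC50ᵦ|, evaluated in fixed order: *activity cliff* (≥ 1
partner active and d ≥ 100 nM), *similarly active* (both active, d <
100 nM), *similarly inactive* (both inactive, d < 100 nM), *soft cliff*
(one active, d < 100 nM); both-inactive pairs with d ≥ 100 nM (possible
when one IC50 was imputed at 100 µM) remain *uncategorized*.  The 100 nM
difference is deliberately interpreted in concentration units because that
is how the rule is stated; ΔpIC50 ≥ D and fold-change ≥ F variants are
selectable by config since the wording admits either reading.  Note the
concentration rule is asymmetric on the log scale: among actives
(IC50 < 3.16 µM on both sides of the 5.5 threshold, gaps of 100 nM are
easy to exceed) it fires far more often than a 1-log-unit rule would.
Frequent-cliff transformations require ≥ 10 pairs and ≥ 5 % cliffs.
Fragments on either side of passing transformations are pooled uniquely
(attachment points capped with hydrogen) and summarized physicochemically
(median SlogP and the descriptor panel).

## Substructure feature importance

Molecules are fingerprinted by counting distinct matches of each pattern in
a named SMARTS catalog shipped with the package (97 functional-group keys,
`name<TAB>SMARTS<TAB>positive-example` lines; every entry is tested against
its own documented example).  The workflow is strictly leakage-free: a 7:3
stratified split on (enzyme, activity class) happens first, then invariant
columns are dropped and, scanning in descending-variance order (ties by
name), any column with |Spearman ρ| > 0.7 to an already-kept column is
removed — the kept list is applied unchanged to the test rows.  SMOTE
raises minority-class counts by sampling xᵢ + u·(x_nn − xᵢ), u ~ U(0,1),
x_nn among the k = 5 nearest same-class neighbours, on training rows only.
Model selection is nested cross-validation on macro-F1 (5 inner folds for
the grid search, 10 outer folds for the unbiased estimate); the default
family is a random forest, with min-max scaling applied only to families
that need it (fit on training folds).  Per-enzyme binary activity models
are the default target; the multi-class variant is available.  A class
whose test precision or recall falls below a configurable floor (default
0.5) is flagged unreliable and skipped in attribution — the expected fate
of a 15-molecule dataset.

Shapley attributions come from an in-package path-dependent TreeSHAP for
sklearn tree ensembles: node cover fractions approximate conditional
expectations along decision paths, and attributions satisfy local accuracy
(per sample, Σ attributions = prediction − expected value) to machine
precision; the implementation is verified against brute-force Shapley
subset enumeration on small trees.  Features are ranked by mean
|attribution|.

## Synthetic benchmark

The generator enumerates molecules as scaffold templates (ring-system
SMILES with numbered attachment points) × substituents from an R-group
table, with activity

    pIC50 = baseline(scaffold) + Σ contribution(substituent)
            + cliff bonus(scaffold, position, substituent) + N(0, σ)

so every single-substituent matched pair and every rule-driven cliff is
known exactly.  Defaults emulate the statistical shape of a curated ENR
collection: enzyme datasets of 1000/445/51/15 (InhA/FabI/FabK/FabV),
skewed scaffold weights (0.30 → 0.02 over eight two-ring scaffolds),
noise-free pIC50 spanning ≈ 3.8–9.5 with ≈ 38 % active at the 5.5
threshold (the curated collection shows 39 % over 3.5–9.7), σ = 0.3 pIC50
units (typical inter-assay reproducibility), three context-specific cliff
rules with bonuses ≥ 2 log units, and 10 % of inactive-valued records
emitted as qualitative inactives to exercise imputation.  Sampling is
uniform-without-replacement within a scaffold; scaffold identity is
multinomial in the configured weights until a deck is exhausted.  Two
deliberate design constraints: attachment points are placed inequivalently
(para/meta) so each combo is a unique canonical molecule, and the default
R-group table contains only heavy-atom substituents because a hydrogen
"substituent" leaves no bond the fragmenter may cut, which would make such
pairs undiscoverable by any heavy-bond MMP engine.

What passing recovery tests show: the fragment-and-index machinery, the
pair constraints and the cliff taxonomy are internally consistent and find
what was planted.  What they do not show: behaviour on real assay
heterogeneity (mixed protocols, censored values), scaffold spaces with
macrocycles or fused ring systems absent from the templates, or catalog
coverage of exotic chemotypes — the synthetic molecules are small
(≤ ~25 heavy atoms) and built from eight two-ring cores.

## Numerical and degenerate-input conventions

Identical seeds give byte-identical outputs end-to-end (a single seeded
generator per stage; the report JSON contains no timing).  Degenerate
inputs raise typed errors rather than returning sentinel numbers: constant
vectors for normality/correlation, empty groups for rank tests, n < 2
entropy windows, empty chemotype subsets, all-invariant feature matrices.
Singleton clusters and groups get flagged `None` statistics, not zeros.
The MMP Tanimoto gate is strict (> 0.56) while Butina neighbourhood is
inclusive (≥ 0.75), each following its stated definition.

## Known limitations

* Exact MCS is exponential in the worst case; the 10 s per-cluster timeout
  yields a flagged partial result on pathological clusters.
* The substructure catalog is intentionally compact (97 keys); feature
  counts and kept-column counts are properties of the catalog and dataset,
  not universal constants.
* Path-dependent TreeSHAP distributes attribution among perfectly
  correlated features according to tree structure, not symmetrically; an
  interventional variant would need a background dataset.
* The concentration-based cliff rule combined with 100 µM imputation
  leaves both-inactive/large-gap pairs uncategorized by design.
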