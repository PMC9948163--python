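# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic data generator does and does not
emulate, and the known limitations.

## Curation

An assay record is *essential* when it carries an IC50 or pChEMBL value
**and** an exact `"="` relation; everything else (missing potency,
censored `>`/`<` measurements) is removed first. Deduplication by
molecule identifier keeps the **first** occurrence in file order — the
choice is arbitrary but deterministic; a `dedup="median"` option instead
aggregates the pIC50 of duplicate records by median, for users who prefer
reconciliation over reproducibility of row provenance.

pIC50 is −log₁₀(IC50 in mol/L), i.e. 9 − log₁₀(IC50/nM). When a record
carries both a pChEMBL value and a raw value, the pChEMBL value wins
(it is the database's curated quantity); disagreements above 0.01 log
units are logged. Non-positive values, unknown units and unparsable
SMILES exclude the record, with counts reported in the curation log.

Class boundaries tile the real line: potent [8, ∞), active [7, 8),
intermediate [6, 7), inactive (−∞, 6). "Between 7 and 8" is read as
half-open so every finite pIC50 gets exactly one label and the boundary
value 8 belongs to potent.

Steroid flagging uses a gonane (6-6-6-5 fused tetracycle) substructure
query with generic atoms and bonds, so aromatic A-rings (estradiol) and
heteroatom-substituted cores still match. The trade-off is that any
6-6-6-5 fused system is called steroidal; the pattern is an argument and
can be swapped for a stricter all-carbon query.

## Property EDA and PCA

The six properties are RDKit's MolWt, Crippen MolLogP, Lipinski H-bond
acceptor/donor counts, rotatable-bond count and Ertl TPSA. Log P in
particular is an atomic-contribution estimate; other tools (fragment- or
descriptor-based estimators) give systematically different values, so
absolute log P levels are comparable only within one backend.

Skewness is the adjusted Fisher–Pearson sample skewness and kurtosis the
excess (Fisher) sample kurtosis — the common spreadsheet defaults. Both
are reported as NaN (and logged) for constant or n ≤ 2 samples rather
than raising, since a constant property within one group is a data
feature, not an error.

The Mann–Whitney U test is two-sided throughout. For small comparisons
(smaller group ≤ 8 and at most 2×10⁶ assignments) the p-value is computed
by exact enumeration over all group assignments of the pooled midranks;
the U distribution under H0 is symmetric about n₁n₂/2 even with ties, so
the two-sided p is the probability mass at least as far from the centre
as observed. Larger comparisons use the tie-corrected normal
approximation. The enumeration bound exists because exact enumeration is
combinatorially infeasible when only one group is small but the other is
large; the bound is a tractability guard, not a statistical choice.

PCA standardises each property to zero mean and unit variance (ddof = 1)
before the eigendecomposition — the six properties have incommensurate
units, so the correlation structure is the meaningful object. Components
are ordered by decreasing explained variance, loadings are unit-norm
eigenvector coefficients, and each component is sign-flipped so its
largest-magnitude loading is positive (eigenvectors are defined up to
sign; this rule makes outputs reproducible across linear-algebra
backends). Constant columns are rejected with an instruction to remove
them.

## Scaffolds

Murcko scaffolds come from RDKit's implementation (rings + linkers,
terminal side chains pruned; exocyclic multiple-bonded atoms are retained,
per RDKit convention). The cyclic skeleton applies the generic transform
— every atom to carbon, every bond to single — which is idempotent and
deliberately blind to heteroatoms and aromaticity, so pyridine and
benzene share one CSK. Acyclic molecules have an empty scaffold; they are
pooled under a single flagged record, counted in Ns but excluded from
Ncsk (a skeleton of nothing is undefined).

Diversity ratios are reported rounded to three decimals with raw counts
retained. Per-class reports are computed on each class subset
independently, so class counts can sum to more than the complete set when
scaffolds are shared across classes.

The enrichment factor treats "active" as the group-1 superset
(potent + active). Identities that follow from the definition — EF = 0
for scaffolds without group-1 members, frequency-weighted mean EF = 1
over the dataset — are covered by tests.

R-group decomposition labels substitutable scaffold positions (atoms with
at least one hydrogen) R1…Rk by the scaffold's canonical atom ranking, so
labels are stable across members and runs without depending on any
tool-internal numbering. Substituents are extracted by core removal;
unsubstituted positions map to `[H]`. For symmetric scaffolds the
assignment of equivalent positions is fixed by the first substructure
match, which is deterministic for canonical input.

## Fingerprints and the landscape

ECFP4 is the Morgan fingerprint (radius 2) hashed to 2048 bits; MACCS is
the 166-key set (RDKit's placeholder bit 0 dropped). The `pubchem` kind
is an 881-position substructure-key fingerprint laid out like the
PubChem/CACTVS fingerprint — hierarchic element counts, ring counts by
size and composition, bonded atom pairs and neighbourhoods, and a
functional-group panel — generated as a deterministic catalogue at import
time. It is **not** bit-compatible with CACTVS/PaDEL: the landscape and
QSAR statistics are fingerprint-pluggable, and `register_fingerprint`
accepts an external generator where bit-exact parity with another tool is
required.

All n(n−1)/2 pairs are enumerated exactly (≈1.4 M pairs at n ≈ 1700 —
minutes on one CPU, no approximation warranted). Quadrant thresholds are
strict: a cliff needs similarity > 0.9 **and** ΔpIC50 > 2. The quadrant
naming follows the standard SAS-map convention — smooth (high sim, low
Δ), cliff (high sim, high Δ), scaffold hop (low sim, low Δ), nondescript
(low sim, high Δ).

SALI = Δactivity / (1 − sim) is undefined at sim = 1; such pairs are
flagged `duplicate-structure`, excluded from SALI rankings, but still
count as activity cliffs when their potency gap exceeds the threshold —
two molecules a fingerprint cannot distinguish yet with very different
potencies are precisely the most informative discontinuities.

Consensus cliffs are the intersection of the per-fingerprint cliff sets.
Generators are ranked by cliff-pair count (descending) with ties broken
by molecule id; ranks are 1-based positions in that order.

## QSAR

Random oversampling duplicates uniformly sampled molecules (with
replacement, seeded) within each minority class until all classes match
the majority size; originals are always retained. Feature selection is
two-stage: population variance < 0.1 first, then a forward scan that
drops the **later** column of any pair with |r| > 0.95 (for binary bits
Pearson r is the phi coefficient and is computed directly from the 0/1
matrix). The retained-column list is recorded and re-applicable to new
data.

The split is stratified 80:20 with stratified 10-fold CV inside the
training portion, everything seeded (default 42). The bench fixes the
hyperparameters per algorithm: 500 trees and a fixed random state for the
tree ensembles, max_features = 3 and Gini for the random forest, one
hidden layer of 100 units for the MLP, library defaults elsewhere; each
classifier is wrapped one-vs-rest. A failing algorithm is reported as a
flagged row and the bench continues.

Two orders of operations are supported because the common literature
protocol — oversample, select features, then split — leaks duplicated
molecules across the train/test boundary and inflates test scores. The
default `safe` mode splits first, fits feature selection on the training
portion, and oversamples only inside the training portion and inside each
CV training fold; `paper-parity` mode preserves the conventional order
for comparability and should be read with that bias in mind.

Metrics come from the full K×K confusion matrix: accuracy = trace/total;
macro recall averages per-class recall with absent classes contributing 0
(logged); MCC is the R_K generalisation
(c·s − **t**·**p**) / √((s² − Σp²)(s² − Σt²)), which reduces to the
binary MCC for K = 2 and is 0 when the denominator vanishes (e.g. a
single predicted class).

## Synthetic data

The generator emulates the *shape* of a ChEMBL IC50 export: scaffold
families with R-group variants, lognormal IC50s, duplicate rows, invalid
records, and planted cliffs. Defaults are the package's reference study
conditions: 8 families × 40 members, family mean pIC50s
(5.0, 5.5, 6.3, 6.6, 7.3, 7.6, 8.3, 8.6) spanning all four classes with a
within-family SD of 0.3 log units, 30 duplicates, 10 missing-value plus
10 `">"`-relation records, and 10 cliff pairs at ΔpIC50 = 2.5 (set by
construction, not sampled, so cliff detection is a sharp pass/fail test).
About 30 % of rows also carry a pChEMBL value (the pIC50 rounded to two
decimals), exercising the pChEMBL-priority path.

Each family template is a drug-sized core (35–41 heavy atoms) carrying
two symmetry-equivalent para-substituted aryl arms (slots x1, x2) and one
core slot (y); members draw R-groups from an 11-entry vocabulary (H,
methyl, ethyl, F, Cl, Br, nitrile, hydroxyl, trifluoromethyl, methoxy,
amino). A planted cliff fixes x1 = F and swaps F → Cl at x2: every ECFP4
environment of the swapped-out fluorine persists on the twin arm, so the
pair's Tanimoto similarity stays above 0.9 for every choice of y — a
construction that yields controllably high similarity without optimising
against any particular fingerprint. Because all R-groups are terminal,
every family member shares one Murcko scaffold, and the eight templates
have pairwise-distinct cyclic skeletons, so scaffold analysis recovers
the family count exactly.

What the generator does **not** emulate: real AR-antagonist property
distributions, scaffold frequency tails (real sets have hundreds of
scaffolds and many singletons; the synthetic set has 8 and none), assay
noise between duplicate measurements, salts/mixtures, or strong class
imbalance (the default family means give roughly balanced classes, so
the oversampler's behaviour under heavy imbalance is exercised by
constructed unit fixtures instead). Passing tests therefore demonstrate
the correctness of the machinery — filters, counts, landscape geometry,
leakage-safe evaluation — not performance on real pharmacology.

## Problem sizes and seeds

The reference synthetic run uses 320 curated molecules (51 040 pairs per
fingerprint), a 256/64 split, and the four fast tree ensembles with
10-fold CV in the acceptance script; the full 12-algorithm bench runs on
smaller fixtures in the test suite. These sizes make the complete suite
and the acceptance run finish in a few minutes on one CPU while keeping
every planted-structure check exact. All stochastic steps take an
explicit seed; a single `--seed` drives the acceptance script end to end.

## Known limitations

* Log P and the 881-bit key set are backend-specific; numbers are not
  comparable across tools at the bit/decimal level.
* Steroid detection by generic gonane substructure over-matches unusual
  6-6-6-5 fused heterocycles.
* R-group labels on highly symmetric scaffolds depend on the (fixed)
  first substructure match, not on chemical equivalence classes.
* `paper-parity` QSAR scores are optimistically biased by design; use
  them only to compare against results produced with the same protocol.
* The exact Mann–Whitney enumeration is capped at 2×10⁶ assignments;
  beyond that the asymptotic approximation is used even for a small
  group.
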