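# chemlandscape

A tested, reusable pipeline for the cheminformatic analysis of IC50
bioactivity data — from raw assay-table curation through chemical-space
exploration, Murcko-scaffold diversity, structure–activity landscapes and
activity cliffs, to a multiclass QSAR classifier bench. It is aimed at
computational medicinal chemists who work with ChEMBL-style exports (the
motivating use case is androgen-receptor antagonist SAR) and who want each
analysis step to be scriptable, seeded and unit-tested rather than driven
through a GUI.

Every stage can run entirely on synthetic ChEMBL-shaped data with known
ground truth (planted duplicates, invalid records and activity cliffs), so
the whole pipeline is verifiable without downloading anything.

## What it computes

**Curation.** Records without an IC50/pChEMBL value or with a qualified
relation (`>`, `<`) are dropped; molecules are deduplicated by identifier;
potencies are converted to pIC50 = −log₁₀(IC50 in mol/L) and binned:
potent (pIC50 ≥ 8), active ([7, 8)), intermediate ([6, 7)), inactive (< 6).
Group 1 = potent + active, group 2 = the rest. Molecules containing the
gonane 6-6-6-5 ring system are flagged steroidal.

**Chemical space.** Six properties (MW, log P, nHA, nHD, nRot, TPSA) are
summarised per group (min/max/median/mean/skewness/kurtosis) with two-sided
Mann–Whitney U tests, and projected by PCA on z-scored properties.

**Scaffolds.** Bemis–Murcko scaffolds and cyclic skeletons (CSKs; every
atom → C, every bond → single) give the diversity counts N, Ns, Nss, Ncsk
and their ratios, plus per-scaffold enrichment factors

    EF(s) = (group-1 fraction among members of s) / (group-1 fraction overall)

and R-group SAR tables via scaffold-based decomposition.

**Landscape.** For all molecule pairs and three fingerprints (ECFP4,
MACCS, an 881-bit PubChem-layout key set), Tanimoto similarity and
|ΔpIC50| define the SAS-map quadrants (activity cliff: similarity > 0.9
and ΔpIC50 > 2) and the structure–activity landscape index

    SALI = |A(m1) − A(m2)| / (1 − sim(m1, m2)),

undefined for structurally degenerate pairs (sim = 1). Cliffs found under
every fingerprint are consensus cliffs; molecules recurring in many cliff
pairs are cliff generators.

**QSAR.** Random oversampling to the majority class, variance (< 0.1) and
correlation (> 0.95) feature filters, a stratified 80:20 split with
10-fold CV, and twelve one-vs-rest classifiers (DT, ET, RF, GB, LGBM,
XGB, MLP, LR, KNN, SVM, NB, GP) scored by accuracy, macro recall and the
multiclass (R_K) Matthews correlation coefficient. The default mode is
leakage-safe (oversampling and feature selection fitted on training data
only); `paper-parity` mode reproduces the widespread
oversample-then-split protocol for comparability.

## Worked example

```python
from chemlandscape import (SynthConfig, generate_dataset, curate,
                           diversity_metrics, sas_map, ac_pairs, run_qsar)

records, truth = generate_dataset(SynthConfig())     # default study conditions
curated, log = curate(records)
print("curation:", log.as_dict())

div = diversity_metrics(curated, by_class=False)["complete"]
print(f"diversity: N={div.n} Ns={div.ns} Nss={div.nss} Ncsk={div.ncsk}")

pairs = sas_map(curated, "ecfp4")
acs = ac_pairs(pairs)
planted = {tuple(sorted(p)) for p in truth.planted_cliff_pairs}
print(f"landscape: {len(pairs)} pairs, {len(acs)} ECFP4 cliffs, "
      f"{len(planted & acs)}/10 planted cliffs recovered")

result = run_qsar(curated, kind="pubchem", mode="safe", folds=0,
                  algorithms=["RF", "ET", "XGB", "LGBM"])
best = result.best()
print(f"qsar: best={best.algorithm} test accuracy={best.test.accuracy:.3f} "
      f"(majority baseline {result.majority_baseline:.3f})")
```

prints

```
curation: {'n_input': 370, 'n_essential_removed': 20, 'n_duplicate_removed': 30,
           'n_parse_failed': 0, 'n_conversion_failed': 0, 'n_curated': 320}
diversity: N=320 Ns=8 Nss=0 Ncsk=8
landscape: 51040 pairs, 10 ECFP4 cliffs, 10/10 planted cliffs recovered
qsar: best=RF test accuracy=0.719 (majority baseline 0.250)
```

The 370 generated rows contain exactly 20 invalid records and 30
duplicates, all removed by curation; the 320 curated molecules collapse to
the 8 planted scaffold families; all 10 planted activity cliffs (single
R-group swaps with ΔpIC50 = 2.5) are recovered as ECFP4 cliffs; and the
best ensemble classifier clearly beats the majority-class baseline on the
held-out 20%.

The same stages are available from the shell:

```sh
chemlandscape synth --out table.csv --truth truth.json
chemlandscape curate --in table.csv --out run/curated
chemlandscape eda --in run/curated/curated.csv --out run/eda
chemlandscape scaffolds --in run/curated/curated.csv --out run/scaffolds
chemlandscape landscape --in run/curated/curated.csv --out run/landscape
chemlandscape qsar --in run/curated/curated.csv --out run/qsar
chemlandscape run --out run/all            # full pipeline + manifest.json
```

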