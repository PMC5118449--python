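# liversar

Structural-alert SAR modeling of drug-induced liver injury (DILI).

Hepatotoxicity is among the hardest endpoints to predict in silico: the
mechanisms are heterogeneous (steatosis, cholestasis, fibrosis,
idiosyncratic reactions), there is no single reliable biomarker, and the
public data are noisy. `liversar` implements a rule-based approach to the
problem: a library of **structural alerts** (SAs) — SMARTS substructure
patterns each labeled *hepatotoxic* or *non-hepatotoxic* — screened
against query molecules and combined by a deliberately conservative
decision tree. The package bundles a 13-alert expert rule set (11
hepatotoxic classes such as sulphonamides, β-lactam penicillins,
tricyclic antidepressants, nitrosoureas; 2 non-hepatotoxic classes,
steroids and cephalosporins) and provides the full machinery used to
build such models:

- **chem_io** — SMILES/SDF parsing, canonicalization (largest organic
  fragment), binary activity-label schemes (0/1, FDA A/I/M,
  DILI-concern categories).
- **curation** — multi-source merging with duplicate detection by
  canonical-structure identity and concordance filtering (duplicated
  compounds with agreeing labels are kept once; disagreeing ones are
  removed), overlap subtraction, seeded random train/test splits.
- **alert_engine** — rule-set loading (bundled and CSV/JSON files),
  SMARTS normalization, substructure screening.
- **classifier** — the decision tree.
- **evaluation** — confusion counts, accuracy, sensitivity, specificity,
  MCC, coverage, per-alert statistics, and the likelihood ratio.
- **fragment_miner** — automatic alert extraction: exhaustive
  fragmentation (acyclic single-bond cuts; rings intact),
  likelihood-ratio validation of every fragment, greedy rule selection
  with a 70% TP retention threshold, and redundancy pruning against
  manual alerts.
- **similarity_clustering** — a composite similarity index (fingerprint
  + size + heteroatom profile + functional-group keys) with iterative
  cluster refinement, an average-similarity filter, single-linkage
  super-clusters, and maximum-common-substructure scaffold suggestion.
- **synthetic_fixtures** — labeled molecule generators with planted
  alerts at controlled penetrance/contamination, for testing everything
  above without external data.

## The model

Write P and N for the numbers of hepatotoxic ("positive") and
non-hepatotoxic compounds. Screening a molecule against the rule set
yields counts (n⁺, n⁻) of matched hepatotoxic and non-hepatotoxic
alerts, and the verdict is

- **unknown** if n⁺ = n⁻ = 0 (no evidence — the absence of an alert is
  not proof of safety);
- **non-hepatotoxic** if n⁻ > n⁺;
- **hepatotoxic** otherwise — ties go to the toxic call, because
  overestimating hepatotoxicity is preferable to missing an unsafe
  compound.

Performance over the predicted (non-unknown) compounds uses the standard
statistics

    accuracy   = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the unpredicted fraction reported separately as coverage. Mined
fragments are scored with the likelihood ratio

    LR = (TP / FP) × (N / P)

which measures class enrichment corrected for class balance (LR = ∞ when
FP = 0).

## Worked example

```python
import liversar as lv

rules = lv.load_table1_alerts()          # 13 bundled expert alerts
ds, expected = lv.truth_table_fixture()  # 4 engineered molecules

for p in lv.predict_dataset(ds, rules):
    print(p.record_id, p.n_pos_alerts, p.n_neg_alerts, p.verdict)
```

prints

```
tt_unmatched 0 0 unknown
tt_one_pos 1 0 Activity.HEPATOTOXIC
tt_tie 1 1 Activity.HEPATOTOXIC
tt_majority_neg 1 2 Activity.NON_HEPATOTOXIC
```

— ethanol matches nothing (unknown); benzenesulfonamide trips the
sulphonamide alert; a pyridyl steroid ties one toxic against one safe
alert and is conservatively called hepatotoxic; a molecule carrying the
steroid and cephalosporin cores plus a pyridine is outvoted 2–1 into the
safe verdict.

Evaluating confusion counts:

```python
from liversar.evaluation import ConfusionCounts, percent
c = ConfusionCounts(tp=263, fp=72, tn=144, fn=18, n_unknown=263)
print(percent(lv.specificity(c)), round(lv.mcc(c), 2))   # -> 67 0.64
```

A command-line interface mirrors the library (`liversar curate`,
`screen`, `predict`, `evaluate`, `mine`, `cluster`, `fixtures`,
`reproduce`); run `liversar --help`.

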