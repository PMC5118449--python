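# Methods

## The rule-based model

The classifier is a structural-alert vote. A structural alert is a
substructure query with a predicted activity (hepatotoxic or
non-hepatotoxic) and a provenance (manual, i.e. expert-curated, or
statistical, i.e. mined from training data). A molecule "contains" an
alert at most once — multiplicity of embeddings is ignored — so
per-alert occurrence statistics count compounds, and manual and
statistical alerts carry equal weight in the vote. The decision tree is
exactly three-valued: no matches → unknown (non-predicted); strictly
more non-hepatotoxic than hepatotoxic matches → non-hepatotoxic;
otherwise → hepatotoxic. Ties are resolved toward toxicity by design:
the model's intended use is screening, where a false alarm is cheaper
than a miss. The expected cost of this choice is visible in evaluation:
sensitivity stays high while specificity degrades, and that is the
documented trade-off, not a defect.

Unknown verdicts are excluded from accuracy, sensitivity, specificity
and MCC and reported separately as coverage. This matches the way the
underlying performance tables are computed (their denominators are the
predicted compounds only) and keeps "the model declines to answer"
distinct from "the model answers wrongly". Integer percentages are
reported with round-half-up; MCC with two decimals. MCC returns 0 when
any denominator factor vanishes — the standard convention; the statistic
is uninformative there.

## Pattern semantics

Expert alerts are SMARTS, interpreted under standard Daylight semantics
by RDKit after a light normalization: internal whitespace (typographic
artifacts of printed tables) is stripped and the `^*^` wildcard markup
is rewritten to `[*]`. Two transcription risks are handled explicitly:

- Every bundled alert carries a positive- and a negative-control
  molecule, and rule-set loading fails fast if a control stops matching.
  This guards against silent aromaticity/dialect drift across toolkit
  versions.
- Several printed patterns write heteroaromatic ketone rings
  (4-quinolones, pyrimidinones) with aliphatic atoms. RDKit's default
  aromaticity model perceives those rings as aromatic in the real drugs,
  so the patterns cannot match, e.g., marketed fluoroquinolones under
  this toolkit. The patterns are kept verbatim; their control molecules
  are synthetic non-aromatized analogues (a quinolinium construct for
  the fluoroquinolone alert, a dihydropyrimidinone nucleoside for the
  nucleoside-analog alert). This is a known limitation of the alert
  transcription, not of the engine.

Statistical alerts are fragments written as SMILES. They are matched as
hydrogen-agnostic skeletal queries: explicit hydrogen counts (an
artifact of bond cutting — freed valence is emitted as H) and residual
radical annotations are cleared before matching, so a fragment always
matches every molecule it was cut from, however substituted. The same
compiled-query semantics are used during mining, validation and
screening, so a mined rule's statistics are reproducible by the alert
engine.

## Dataset curation

Compound identity is canonical-SMILES equality on the largest organic
fragment (salts and solvates compare by parent structure). Exact
identity is deliberately conservative: similarity-based duplicate
detection depends on unpublished thresholds, while canonical identity is
reproducible across runs and toolkits. Merging two labeled sources keeps
concordant duplicates once (provenance concatenated) and removes
conflicting duplicates entirely — a contested label is treated as worse
than no data. Stereochemistry is preserved as given; how the original
curation treated stereoisomers and salts is unrecorded, so this is a
package decision. The train/test split is plain random (the original
split was), with the seed an explicit required parameter since the
original membership is unrecoverable; a stratified option exists but is
off by default. Split sizes use round(n·fraction) half-up, giving the
documented 760/190 at n = 950, fraction 0.8.

## Fragment mining

Enumeration cuts acyclic single bonds only. Ring systems and atoms
joined by acyclic multiple bonds are contracted into block nodes; the
remaining bonds form a tree, and every connected subtree whose total
heavy-atom count lies in `[min_atoms, max_atoms]` (default 2–18) is a
fragment. This keeps the fragment space finite, chemically meaningful
(rings are never broken) and exhaustively enumerable; each subtree is
generated exactly once by rooted enumeration at its minimum node.

Validation counts, for every distinct fragment, the training molecules
of each class containing it. The fragment's label is the class it is
enriched in *relative to class sizes* (ties to hepatotoxic), and its
score is the likelihood ratio LR = (TP/FP)·(negatives/positives), with
an infinity sentinel at FP = 0. Selection is greedy sequential covering:
candidates sorted by LR descending (ties: higher support, then fewer
atoms, then lexicographic), accepted when TP% ≥ 70 (the retention
threshold, applied to both labels symmetrically — for non-hepatotoxic
rules TP% reads as TN%), support ≥ `min_support`, LR ≥ `lr_min`, and at
least one not-yet-covered training molecule of the rule's own class is
gained. The `max` / `optimal` / `min` modes map to (3, none), (5, 2) and
(8, 5) for (min_support, lr_min); these presets are this package's
defaults — the corresponding settings of the original mining tool are
documented only in an external reference. Redundancy pruning removes any
statistical alert whose training coverage is a (non-empty) subset of a
same-label manual alert's coverage; empty-coverage alerts are retained,
since the vacuous subset relation would otherwise delete every
non-matching rule.

## Similarity and clustering

The similarity index is a weighted sum of four components in [0, 1]:
Morgan fingerprint (radius 2, 2048 bits) Tanimoto; size agreement
1 − |nA − nB|/max(nA, nB) over heavy atoms; Tanimoto over heteroatom
element multisets (both empty → 1); and Tanimoto over a fixed list of 20
functional-group structural keys (both empty → 1). Default weights
0.6 / 0.15 / 0.1 / 0.15: the original index's weights are unpublished,
so these are package choices exposed in `SimilarityConfig`, preserving
the described architecture (one fingerprint plus three structural-key
descriptors). The index is symmetric, bounded, and exactly 1 on
identical canonical structures.

Clustering starts from all-singletons and sweeps compounds (in a
seed-shuffled order) to the cluster maximizing net cohesion
Σ(s_ij − t) over members, where t is the cohesion threshold (default
0.5); leaving as a singleton scores 0, and ties resolve toward staying,
then the lowest cluster id. Each applied move strictly increases the
global objective J = Σ_{within-cluster pairs}(s_ij − t), so the
iteration terminates and the cluster count is emergent — there is no
fixed K. The published description of the refinement ("compounds are
iteratively moved … until no further optimization step is possible")
does not pin down the objective; this formulation was chosen because it
realizes that description with guaranteed monotone termination and full
determinism. Clusters with mean pairwise similarity below 0.7 are
discarded; survivors are grouped into super-clusters by single linkage
on inter-cluster mean molecule similarity. Scaffold suggestion is
RDKit's maximum common substructure, returned only when it has ≥ 3 heavy
atoms — smaller cores are not an unambiguous chemical motif.

## Synthetic fixtures

The generator emulates the shape of the study data: a near-balanced
binary-labeled set (defaults 510 positive / 440 negative) where planted
scaffolds occur in positives with probability `penetrance` (default 0.9)
and in negatives with probability `contamination` (default 0.05).
Molecules are assembled by single-bond attachment of scaffolds, N- and
S-free decoys, and 0–3 decorations (methyl, ethyl, isopropyl, F, Cl,
OH), so every structure parses and no decoy combination can accidentally
embed a bundled alert. What the fixtures do **not** emulate: real
pharmacophore diversity, correlated label noise, the idiosyncratic
component of DILI, or literature-derived "negative by absence of
evidence" labels. Passing tests on fixtures therefore demonstrate
algorithmic correctness (recovery of a signal known to be present at a
known rate), not clinical predictivity. Manifests record realized (not
nominal) per-scaffold match counts, recounted by substructure matching,
so tests compare against exact truths.

## Problem sizes and numerical choices

The test suite and the acceptance script use 50+50-molecule sets for
miner recovery (ten seeds), ≤ 12-molecule instances for clustering
oracle comparisons, and one 950-molecule set for the end-to-end screen —
sizes at which every brute-force oracle (all-pairs duplicate detection,
exhaustive connected-subgraph enumeration, best 2-partition by
enumeration, transitive-closure components) is exactly computable, so
the implementations are checked against independent reimplementations
rather than against themselves. Seeds are explicit everywhere;
enumeration, selection and clustering are deterministic given input
order and seed. Degenerate inputs have documented behavior: empty
profile → unknown verdict; no predicted compounds → metric errors (not
NaNs); FP = 0 → infinite LR; zero-occurrence alerts report TP% as
not-applicable.

## Known limitations

- The bundled alert SMARTS are transcriptions; two of them cannot match
  aromatized drug classes under RDKit perception (see Pattern
  semantics).
- Exact-identity duplicate detection will miss tautomer/salt-form
  duplicates that a fingerprint-similarity tool would flag.
- The miner targets behavioral equivalence with likelihood-ratio rule
  extraction, not byte equivalence with any particular tool's output;
  mode presets and the fragmentation scheme are this package's
  interpretations.
- The similarity-index weights and cohesion threshold are package
  defaults, not published values; published cluster counts and
  similarity ranges are not reproducible without them.
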