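"""Dataset assembly: duplicate resolution, concordance merging, splits.

Multi-source DILI datasets overlap heavily (the two literature sources the
model was built from shared ~17% of their compounds).  Duplicates are
detected by canonical-structure identity; duplicated compounds with
concordant labels are kept once, and compounds whose sources disagree are
removed entirely, since a contested label is worse than no compound.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chem_io import (
    Activity,
    LabeledDataset,
    MoleculeRecord,
    ParameterError,
)


@dataclass
class MergeReport:
    """Accounting for a two-dataset concordance merge.

    Each concordant duplicate pair collapses to one record; each
    conflicting pair removes both records, so
    ``n_final = n_input_a + n_input_b - 2*n_conflicting_removed
    - n_concordant_kept``.
    """

    n_input_a: int
    n_input_b: int
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_conflicting_removed: int = 0
    n_concordant_kept: int = 0
    n_final: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_input_a": self.n_input_a,
                "n_input_b": self.n_input_b,
                "n_duplicate_pairs": len(self.duplicate_pairs),
                "duplicate_pairs": self.duplicate_pairs,
                "n_conflicting_removed": self.n_conflicting_removed,
                "n_concordant_kept": self.n_concordant_kept,
                "n_final": self.n_final,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def find_structural_duplicates(
    a: LabeledDataset, b: LabeledDataset
) -> list[tuple[str, str]]:
    """Pairs of (record_id_a, record_id_b) with identical canonical structure.

    Each record appears in at most one pair; matching is first-match in
    input order, which makes the result deterministic.
    """
    by_structure: dict[str, list[str]] = {}
    for rb in b:
        by_structure.setdefault(rb.smiles_canonical, []).append(rb.record_id)
    pairs: list[tuple[str, str]] = []
    for ra in a:
        bucket = by_structure.get(ra.smiles_canonical)
        if bucket:
            pairs.append((ra.record_id, bucket.pop(0)))
    return pairs


def merge_with_concordance(
    a: LabeledDataset, b: LabeledDataset
) -> tuple[LabeledDataset, MergeReport]:
    """Merge two binary-labeled datasets, resolving duplicates by label.

    Duplicate pairs with equal labels are kept once (the record from ``a``,
    with provenance tags concatenated); pairs with conflicting labels are
    excluded entirely.  Non-duplicates pass through unchanged.
    """
    pairs = find_structural_duplicates(a, b)
    report = MergeReport(
        n_input_a=len(a), n_input_b=len(b), duplicate_pairs=pairs
    )
    paired_a = {ra for ra, _ in pairs}
    paired_b = {rb for _, rb in pairs}

    merged: list[MoleculeRecord] = []
    for ra, rb in pairs:
        rec_a, rec_b = a[ra], b[rb]
        if rec_a.activity_label is rec_b.activity_label:
            tags = "+".join(
                t for t in (rec_a.source_tag, rec_b.source_tag) if t
            )
            merged.append(replace(rec_a, source_tag=tags))
            report.n_concordant_kept += 1
        else:
            report.n_conflicting_removed += 1
    merged.extend(r for r in a if r.record_id not in paired_a)
    merged.extend(r for r in b if r.record_id not in paired_b)
    report.n_final = len(merged)
    return LabeledDataset(merged), report


def subtract_overlap(
    candidate: LabeledDataset, reference: LabeledDataset
) -> LabeledDataset:
    """Candidate records whose structure does not occur in ``reference``.

    Used to keep an external validation set disjoint from the data the
    model was trained and tested on.
    """
    known = set(reference.canonical_smiles())
    return LabeledDataset(
        [r for r in candidate if r.smiles_canonical not in known]
    )


def random_split(
    ds: LabeledDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition a dataset into train/test at ``train_fraction``.

    The training size is round(n * fraction) (half up); the same seed
    always reproduces the same membership.  The split is plain random by
    default; ``stratified=True`` applies the same rule per activity class.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ParameterError(
            f"train_fraction must be in (0,1), got {train_fraction}"
        )
    if len(ds) == 0:
        raise ParameterError("cannot split an empty dataset")

    rng = random.Random(seed)

    def _split_ids(records) -> set[str]:
        ids = [r.record_id for r in records]
        n_train = int(math.floor(len(ids) * train_fraction + 0.5))
        return set(rng.sample(ids, n_train))

    if stratified:
        train_ids: set[str] = set()
        for label in (Activity.HEPATOTOXIC, Activity.NON_HEPATOTOXIC,
                      Activity.UNLABELED):
            group = [r for r in ds if r.activity_label is label]
            if group:
                train_ids |= _split_ids(group)
    else:
        train_ids = _split_ids(ds.records)

    train = [replace(r) for r in ds if r.record_id in train_ids]
    test = [replace(r) for r in ds if r.record_id not in train_ids]
    from .chem_io import SetAssignment

    for r in train:
        r.set_assignment = SetAssignment.TRAIN
    for r in test:
        r.set_assignment = SetAssignment.TEST
    return LabeledDataset(train), LabeledDataset(test)
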