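"""Synthetic labeled molecule sets with planted structural alerts.

The generator emulates the shape of the study data — a fairly balanced
binary-labeled drug set (~510 hepatotoxic / 440 non-hepatotoxic) in which
certain substructures are enriched among the positives — without any
claim to drug-likeness beyond valid valence and scaffold diversity.
Positives carry each planted scaffold with probability ``penetrance``,
negatives with probability ``contamination``; the rest of every molecule
is a decoy scaffold with randomized single-attachment decorations, so
every emitted structure parses.

Because the draws are random, the manifest records the *realized*
per-alert match counts (recounted with the substructure engine), so
downstream tests can compare against exact truths rather than nominal
rates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_io import (
    Activity,
    LabeledDataset,
    LiverSarError,
    MoleculeRecord,
    parse_structure,
)
from .alert_engine import RuleSet, load_table1_alerts, screen

__all__ = [
    "PlantedAlert",
    "FixtureSpec",
    "generate",
    "truth_table_fixture",
    "DEFAULT_DECOYS",
]


class FixtureSpecError(LiverSarError):
    """A fixture specification contains unparseable structures."""


@dataclass
class PlantedAlert:
    """A scaffold enriched among positives.

    ``penetrance`` is the probability a positive carries the scaffold,
    ``contamination`` the probability a negative does; a recoverable alert
    needs penetrance > contamination.
    """

    scaffold: str
    penetrance: float = 0.9
    contamination: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.penetrance <= 1.0:
            raise FixtureSpecError("penetrance must be in (0, 1]")
        if not 0.0 <= self.contamination < 1.0:
            raise FixtureSpecError("contamination must be in [0, 1)")


#: N- and S-free decoys: combined with the decoration grammar below they
#: cannot accidentally embed any of the bundled manual alerts.
DEFAULT_DECOYS: tuple[str, ...] = (
    "CCCCCC",
    "C1CCCCC1",
    "c1ccccc1",
    "CCOCC",
    "CC(C)CO",
    "C1CCOC1",
    "CCC(C)CC",
    "COc1ccccc1",
)

#: Single-attachment substituents (attached via their first atom).
DEFAULT_DECORATIONS: tuple[str, ...] = ("C", "CC", "F", "Cl", "O", "C(C)C")


@dataclass
class FixtureSpec:
    """Composition, planted alerts and randomness of a synthetic set."""

    n_pos: int = 510
    n_neg: int = 440
    planted_alerts: list[PlantedAlert] = field(
        default_factory=lambda: [PlantedAlert("NS(=O)(=O)c1ccccc1")]
    )
    decoy_scaffolds: tuple[str, ...] = DEFAULT_DECOYS
    decorations: tuple[str, ...] = DEFAULT_DECORATIONS
    max_decorations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise FixtureSpecError("n_pos and n_neg must be positive")
        for s in list(self.decoy_scaffolds) + [
            p.scaffold for p in self.planted_alerts
        ]:
            if Chem.MolFromSmiles(s) is None:
                raise FixtureSpecError(f"scaffold does not parse: {s!r}")


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [
        atom.GetIdx()
        for atom in mol.GetAtoms()
        if atom.GetTotalNumHs() > 0 and atom.GetFormalCharge() == 0
    ]


def _attach(rng: random.Random, base: Chem.Mol, sub: Chem.Mol) -> Chem.Mol:
    """Join two fragments with one single bond at random H-bearing atoms."""
    base_sites = _attachment_points(base)
    sub_sites = _attachment_points(sub)
    if not base_sites or not sub_sites:
        raise FixtureSpecError("no free valence available for attachment")
    combo = Chem.RWMol(Chem.CombineMols(base, sub))
    a = rng.choice(base_sites)
    b = rng.choice(sub_sites) + base.GetNumAtoms()
    combo.AddBond(a, b, Chem.BondType.SINGLE)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _build_molecule(
    rng: random.Random, spec: FixtureSpec, scaffolds: list[str]
) -> str:
    mol = Chem.MolFromSmiles(scaffolds[0])
    for extra in scaffolds[1:]:
        mol = _attach(rng, mol, Chem.MolFromSmiles(extra))
    for _ in range(rng.randint(0, spec.max_decorations)):
        decoration = Chem.MolFromSmiles(rng.choice(spec.decorations))
        try:
            mol = _attach(rng, mol, decoration)
        except FixtureSpecError:
            break  # no free valence left; molecule is complete
    return Chem.MolToSmiles(mol)


def generate(spec: FixtureSpec) -> tuple[LabeledDataset, dict]:
    """Generate a labeled dataset and its realized-truth manifest.

    Deterministic per seed.  The manifest maps each planted scaffold to
    the exact number of positives and negatives that contain it, counted
    by substructure matching on the emitted structures (attachment and
    decoration can only add atoms, never remove a planted scaffold).
    """
    rng = random.Random(spec.seed)
    records: list[MoleculeRecord] = []
    for label, count, prefix in (
        (Activity.HEPATOTOXIC, spec.n_pos, "POS"),
        (Activity.NON_HEPATOTOXIC, spec.n_neg, "NEG"),
    ):
        for i in range(count):
            planted = [
                p.scaffold
                for p in spec.planted_alerts
                if rng.random()
                < (
                    p.penetrance
                    if label is Activity.HEPATOTOXIC
                    else p.contamination
                )
            ]
            scaffolds = planted or [rng.choice(list(spec.decoy_scaffolds))]
            smiles = _build_molecule(rng, spec, scaffolds)
            records.append(
                MoleculeRecord.from_smiles(
                    record_id=f"{prefix}{i:04d}",
                    smiles=smiles,
                    activity_label=label,
                    source_tag="synthetic",
                )
            )
    ds = LabeledDataset(records)

    manifest: dict = {"seed": spec.seed, "planted": []}
    for p in spec.planted_alerts:
        query = Chem.MolFromSmiles(p.scaffold)
        pos_ids, neg_ids = [], []
        for r in ds:
            mol = Chem.MolFromSmiles(r.smiles_canonical)
            if mol.HasSubstructMatch(query):
                if r.activity_label is Activity.HEPATOTOXIC:
                    pos_ids.append(r.record_id)
                else:
                    neg_ids.append(r.record_id)
        manifest["planted"].append(
            {
                "scaffold": p.scaffold,
                "penetrance": p.penetrance,
                "contamination": p.contamination,
                "realized_pos_matches": len(pos_ids),
                "realized_neg_matches": len(neg_ids),
                "realized_pos_ids": pos_ids,
                "realized_neg_ids": neg_ids,
            }
        )
    return ds, manifest


# -- decision-tree truth-table fixture --------------------------------------

#: Four engineered molecules covering the decision-tree rows against the
#: bundled manual alerts: (0 pos, 0 neg), (1, 0), (1, 1) and (1, 2).
_TRUTH_TABLE = (
    # ethanol: matches nothing
    ("tt_unmatched", "CCO", Activity.NON_HEPATOTOXIC, "unknown"),
    # benzenesulfonamide: sulphonamide alert only
    ("tt_one_pos", "NS(=O)(=O)c1ccccc1", Activity.HEPATOTOXIC,
     "hepatotoxic"),
    # pyridine bolted onto a steroid core: one hepatotoxic vs. one
    # non-hepatotoxic alert; the tie goes to the toxic verdict
    ("tt_tie", "c1ccncc1C1CC2CCC3C(CCC4CCCCC34)C2C1",
     Activity.HEPATOTOXIC, "hepatotoxic"),
    # steroid-acyl cephalosporin with a pyridine: one hepatotoxic vs. two
    # non-hepatotoxic alerts (steroid + cephalosporin)
    ("tt_majority_neg",
     "O=C(NC1C2SCC=C(N2C1=O)C(O)=O)C1CC2CCC3C(CCC4CCCCC34)C2C1c1ccncc1",
     Activity.NON_HEPATOTOXIC, "non_hepatotoxic"),
)


def truth_table_fixture() -> tuple[LabeledDataset, dict[str, str]]:
    """Static four-molecule fixture with expected decision-tree verdicts.

    Returns the dataset and a map record_id -> expected verdict
    ("unknown", "hepatotoxic" or "non_hepatotoxic") under the bundled
    manual rule set.
    """
    records = [
        MoleculeRecord.from_smiles(rid, smi, label)
        for rid, smi, label, _ in _TRUTH_TABLE
    ]
    expected = {rid: verdict for rid, _, _, verdict in _TRUTH_TABLE}
    return LabeledDataset(records), expected
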