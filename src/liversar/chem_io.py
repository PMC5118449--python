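"""Molecule and dataset I/O for the hepatotoxicity SAR pipeline.

Molecules are carried as SMILES and canonicalized with RDKit.  Identity
between compounds (duplicate detection, overlap subtraction) is canonical-
SMILES equality on the largest organic fragment, so salts and solvates
compare by their parent structure.

Datasets are binary-labeled compound lists (hepatotoxic / non-hepatotoxic)
read from a simple CSV dialect or from SDF with an activity property tag.
Rows whose structure cannot be parsed are reported and skipped, never
silently dropped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger("liversar")

# RDKit is chatty about every unparseable SMILES; rejections are reported
# through our own logger instead.
RDLogger.DisableLog("rdApp.error")


class LiverSarError(Exception):
    """Base class for all errors raised by this package."""


class StructureParseError(LiverSarError):
    """A SMILES or SDF record could not be parsed into a molecule."""


class LabelingError(LiverSarError):
    """An activity label token is unknown under the declared scheme."""


class ConfigurationError(LiverSarError):
    """Malformed input file or invalid configuration."""


class EmptyDatasetError(LiverSarError):
    """A dataset read or operation produced zero usable records."""


class ParameterError(LiverSarError):
    """A numeric parameter is outside its valid domain."""


class ConsistencyError(LiverSarError):
    """Cross-referenced objects (predictions vs. labels) do not line up."""


class Activity(str, Enum):
    HEPATOTOXIC = "hepatotoxic"
    NON_HEPATOTOXIC = "non_hepatotoxic"
    UNLABELED = "unlabeled"


class SetAssignment(str, Enum):
    TRAIN = "train"
    TEST = "test"
    EXTERNAL = "external"
    UNASSIGNED = "unassigned"


#: Label value that means "drop this record" (e.g. the FDA "M" marginal
#: class, or LTKB less-DILI-concern compounds).
EXCLUDED = "excluded"

_largest_fragment = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def parse_structure(smiles: str) -> str:
    """Canonicalize a SMILES string.

    The largest organic fragment is kept (salts/mixtures reduce to the
    parent structure) and the RDKit canonical SMILES is returned, so the
    same molecule written two ways yields identical output and the
    operation is idempotent.

    Raises
    ------
    StructureParseError
        If ``smiles`` is empty or does not parse.
    """
    if not smiles or not smiles.strip():
        raise StructureParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        mol = _largest_fragment.choose(mol)
    return Chem.MolToSmiles(mol)


def normalize_label(raw: str, scheme: str = "binary_01") -> str:
    """Map a raw activity token to the binary hepatotoxicity dichotomy.

    Schemes
    -------
    ``binary_01``
        ``1`` -> hepatotoxic, ``0`` -> non_hepatotoxic.
    ``fda_aim``
        FDA liver adverse-effects coding: ``A`` (active) -> hepatotoxic,
        ``I`` (inactive) -> non_hepatotoxic, ``M`` (marginally active) ->
        excluded.  Marginal compounds are dropped to reduce label
        uncertainty.
    ``dili_concern``
        LTKB benchmark coding: most-DILI-concern -> hepatotoxic,
        no-DILI-concern -> non_hepatotoxic, less-DILI-concern -> excluded
        (only the two extreme classes are kept).

    Returns ``Activity.HEPATOTOXIC``, ``Activity.NON_HEPATOTOXIC`` or the
    string ``"excluded"``.
    """
    token = raw.strip().lower().replace("_", "-")
    if scheme == "binary_01":
        mapping = {"1": Activity.HEPATOTOXIC, "0": Activity.NON_HEPATOTOXIC}
    elif scheme == "fda_aim":
        mapping = {
            "a": Activity.HEPATOTOXIC,
            "i": Activity.NON_HEPATOTOXIC,
            "m": EXCLUDED,
        }
    elif scheme == "dili_concern":
        mapping = {
            "most-dili-concern": Activity.HEPATOTOXIC,
            "no-dili-concern": Activity.NON_HEPATOTOXIC,
            "less-dili-concern": EXCLUDED,
        }
    else:
        raise ConfigurationError(f"unknown labeling scheme: {scheme!r}")
    try:
        return mapping[token]
    except KeyError:
        raise LabelingError(
            f"unknown label {raw!r} under scheme {scheme!r}"
        ) from None


@dataclass
class MoleculeRecord:
    """One compound: structure, activity label and provenance."""

    record_id: str
    smiles_raw: str
    smiles_canonical: str
    activity_label: Activity = Activity.UNLABELED
    name: str = ""
    source_tag: str = ""
    set_assignment: SetAssignment = SetAssignment.UNASSIGNED

    @classmethod
    def from_smiles(
        cls,
        record_id: str,
        smiles: str,
        activity_label: Activity = Activity.UNLABELED,
        **kwargs,
    ) -> "MoleculeRecord":
        return cls(
            record_id=record_id,
            smiles_raw=smiles,
            smiles_canonical=parse_structure(smiles),
            activity_label=activity_label,
            **kwargs,
        )

    def with_label(self, label: Activity) -> "MoleculeRecord":
        return replace(self, activity_label=label)


@dataclass
class LabeledDataset:
    """An ordered collection of molecule records with unique ids.

    ``n_positive`` / ``n_negative`` are the counts of hepatotoxic and
    non-hepatotoxic records (the P and N of the likelihood-ratio and
    accuracy formulas).
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    #: (row identifier, reason) pairs for inputs rejected during reading.
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dupes = set(), set()
            for i in ids:
                (dupes if i in seen else seen).add(i)
            raise ConsistencyError(f"duplicate record_ids: {sorted(dupes)}")
        self._by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> MoleculeRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def n_positive(self) -> int:
        return sum(
            1 for r in self.records if r.activity_label is Activity.HEPATOTOXIC
        )

    @property
    def n_negative(self) -> int:
        return sum(
            1
            for r in self.records
            if r.activity_label is Activity.NON_HEPATOTOXIC
        )

    def subset(self, record_ids: Iterable[str]) -> "LabeledDataset":
        wanted = set(record_ids)
        return LabeledDataset(
            [r for r in self.records if r.record_id in wanted]
        )

    def by_set(self, assignment: SetAssignment) -> "LabeledDataset":
        return LabeledDataset(
            [r for r in self.records if r.set_assignment is assignment]
        )

    def canonical_smiles(self) -> list[str]:
        return [r.smiles_canonical for r in self.records]


_REQUIRED_COLUMNS = ("id", "smiles", "label")


def read_dataset(
    path: str | Path,
    format: str = "smiles_csv",
    scheme: str = "binary_01",
    sdf_activity_tag: str = "ACTIVITY",
) -> LabeledDataset:
    """Read a labeled dataset from ``smiles_csv`` or ``sdf``.

    The CSV dialect is UTF-8 with a header row and required columns
    ``id,smiles,label``; optional ``name,source,set``.  Records whose
    structure fails to parse, or whose label is excluded under the scheme,
    are logged and collected in ``LabeledDataset.rejected``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    if format == "smiles_csv":
        rows = _read_csv_rows(path)
    elif format == "sdf":
        rows = _read_sdf_rows(path, sdf_activity_tag)
    else:
        raise ConfigurationError(f"unknown dataset format: {format!r}")

    records: list[MoleculeRecord] = []
    rejected: list[tuple[str, str]] = []
    for row in rows:
        rid = row["id"]
        try:
            label = normalize_label(row["label"], scheme)
            if label == EXCLUDED:
                rejected.append((rid, f"label {row['label']!r} excluded"))
                logger.info("record %s excluded by label scheme", rid)
                continue
            records.append(
                MoleculeRecord.from_smiles(
                    record_id=rid,
                    smiles=row["smiles"],
                    activity_label=label,
                    name=row.get("name", ""),
                    source_tag=row.get("source", ""),
                    set_assignment=SetAssignment(
                        row.get("set") or "unassigned"
                    ),
                )
            )
        except (StructureParseError, LabelingError) as exc:
            rejected.append((rid, str(exc)))
            logger.warning("record %s rejected: %s", rid, exc)
    if not records:
        raise EmptyDatasetError(f"no parseable records in {path}")
    ds = LabeledDataset(records)
    ds.rejected = rejected
    return ds


def _read_csv_rows(path: Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required columns {missing} (found {header})"
            )
        return list(reader)


def _read_sdf_rows(path: Path, activity_tag: str) -> list[dict]:
    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        rid = f"sdf{i:05d}"
        if mol is None:
            # surfaced as an unparseable-structure rejection downstream
            rows.append({"id": rid, "smiles": "", "label": ""})
            continue
        if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            rid = mol.GetProp("_Name").strip()
        if not mol.HasProp(activity_tag):
            raise ConfigurationError(
                f"{path}: record {rid} lacks activity property "
                f"{activity_tag!r}"
            )
        rows.append(
            {
                "id": rid,
                "smiles": Chem.MolToSmiles(mol),
                "label": mol.GetProp(activity_tag),
                "name": rid,
            }
        )
    return rows


def write_dataset(ds: LabeledDataset, path: str | Path) -> None:
    """Write a dataset in the smiles_csv dialect (label written as 1/0)."""
    _label_out = {
        Activity.HEPATOTOXIC: "1",
        Activity.NON_HEPATOTOXIC: "0",
        Activity.UNLABELED: "",
    }
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "label", "name", "source", "set"])
        for r in ds:
            writer.writerow(
                [
                    r.record_id,
                    r.smiles_canonical,
                    _label_out[r.activity_label],
                    r.name,
                    r.source_tag,
                    r.set_assignment.value,
                ]
            )


def dataset_from_smiles(
    pairs: Sequence[tuple[str, str, Activity]],
    source_tag: str = "",
) -> LabeledDataset:
    """Build a dataset from (record_id, smiles, label) triples."""
    return LabeledDataset(
        [
            MoleculeRecord.from_smiles(rid, smi, label, source_tag=source_tag)
            for rid, smi, label in pairs
        ]
    )
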