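"""Structural-alert rule sets and SMARTS substructure screening.

A structural alert (SA) is a SMARTS pattern labeled hepatotoxic or
non-hepatotoxic.  The bundled manual rule set holds the 13 expert-derived
alerts (11 hepatotoxic, 2 non-hepatotoxic: steroids and cephalosporins)
with their training-set statistics; statistical rule sets produced by the
fragment miner load from CSV/JSON files in the same dialect.

Patterns are interpreted under standard Daylight SMARTS semantics (RDKit)
after a light normalization that strips typographic whitespace and
rewrites the ``^*^`` wildcard markup as the any-atom primitive.  Every
bundled alert carries a positive- and a negative-control molecule;
rule-set loading fails fast if a control stops behaving, which guards
against silent dialect drift.  A molecule "contains" an alert at most
once: multiplicity of embeddings is ignored, so per-alert occurrence
statistics count compounds.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from rdkit import Chem

from .chem_io import Activity, ConfigurationError, LiverSarError

__all__ = [
    "AlertStats",
    "StructuralAlert",
    "RuleSet",
    "MatchProfile",
    "RuleLoadError",
    "normalize_pattern",
    "match",
    "screen",
    "load_table1_alerts",
]


class RuleLoadError(LiverSarError):
    """A rule file or bundled pattern failed to compile or self-check."""


def compile_smiles_query(fragment: str) -> Optional[Chem.Mol]:
    """Compile a fragment SMILES as a hydrogen-agnostic substructure query.

    Explicit hydrogen counts written into fragment SMILES (an artifact of
    cutting bonds: the freed valence is emitted as an H) are cleared so
    the query matches on the heavy-atom skeleton only — a fragment then
    always matches every molecule it was cut from, however substituted.
    """
    query = Chem.MolFromSmiles(fragment)
    if query is None:
        return None
    for atom in query.GetAtoms():
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
        atom.SetNumRadicalElectrons(0)
    query.UpdatePropertyCache(strict=False)
    for atom in query.GetAtoms():
        atom.SetNumRadicalElectrons(0)
    return query


def normalize_pattern(raw: str) -> str:
    """Clean a printed SMARTS pattern into compilable form.

    Removes internal whitespace (printed patterns carry typographic
    spacing such as ``NS(= O)(= O)c1ccccc1``) and rewrites the printed
    wildcard markup ``^*^`` as the any-atom primitive ``[*]``.

    Raises
    ------
    RuleLoadError
        If the cleaned pattern still fails to compile as SMARTS.
    """
    if not raw or not raw.strip():
        raise RuleLoadError("empty SMARTS pattern")
    cleaned = "".join(raw.split()).replace("^*^", "[*]")
    if Chem.MolFromSmarts(cleaned) is None:
        raise RuleLoadError(f"pattern does not compile as SMARTS: {raw!r}")
    return cleaned


@dataclass
class AlertStats:
    """Per-alert training-set statistics.

    ``occurrences`` counts matched compounds; ``tp`` those whose label
    equals the alert's predicted activity (for non-hepatotoxic alerts this
    is the TN role).  ``tp_pct`` = 100 * tp / occurrences.
    """

    occurrences: int
    tp: int
    fp: int

    def __post_init__(self) -> None:
        if self.occurrences != self.tp + self.fp:
            raise ConfigurationError(
                f"occurrences ({self.occurrences}) != tp+fp "
                f"({self.tp}+{self.fp})"
            )

    @property
    def tp_pct(self) -> Optional[float]:
        if self.occurrences == 0:
            return None
        return 100.0 * self.tp / self.occurrences


@dataclass
class StructuralAlert:
    """A substructure pattern with predicted activity and provenance.

    ``pattern_language`` selects the query semantics: ``smarts`` (expert
    rules, Daylight semantics) or ``smiles`` (mined fragments, matched as
    hydrogen-agnostic substructure queries — the same semantics the miner
    validates fragments under).
    """

    alert_id: str
    pattern_raw: str
    predicted_activity: Activity
    provenance: str = "manual"  # manual | statistical
    description: str = ""
    train_stats: Optional[AlertStats] = None
    positive_control: Optional[str] = None
    negative_control: Optional[str] = None
    pattern_language: str = "smarts"  # smarts | smiles
    pattern_normalized: str = field(default="", compare=False)
    _query: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.pattern_language == "smarts":
            if not self.pattern_normalized:
                self.pattern_normalized = normalize_pattern(self.pattern_raw)
            self._query = Chem.MolFromSmarts(self.pattern_normalized)
        elif self.pattern_language == "smiles":
            self._query = compile_smiles_query(self.pattern_raw)
            if self._query is not None and not self.pattern_normalized:
                self.pattern_normalized = Chem.MolToSmiles(
                    Chem.MolFromSmiles(self.pattern_raw)
                )
        else:
            raise RuleLoadError(
                f"alert {self.alert_id}: unknown pattern language "
                f"{self.pattern_language!r}"
            )
        if self._query is None:
            raise RuleLoadError(
                f"alert {self.alert_id}: pattern does not compile: "
                f"{self.pattern_raw!r}"
            )

    @property
    def query(self) -> Chem.Mol:
        return self._query

    def check_controls(self) -> None:
        """Fail fast if the bundled control molecules misbehave."""
        if self.positive_control is not None:
            mol = Chem.MolFromSmiles(self.positive_control)
            if mol is None or not mol.HasSubstructMatch(self._query):
                raise RuleLoadError(
                    f"alert {self.alert_id}: positive control "
                    f"{self.positive_control!r} no longer matches"
                )
        if self.negative_control is not None:
            mol = Chem.MolFromSmiles(self.negative_control)
            if mol is None or mol.HasSubstructMatch(self._query):
                raise RuleLoadError(
                    f"alert {self.alert_id}: negative control "
                    f"{self.negative_control!r} matches but should not"
                )


def match(molecule: str | Chem.Mol, alert: StructuralAlert) -> bool:
    """True iff the alert's SMARTS has at least one embedding.

    Accepts a SMILES string or an RDKit molecule.  Multiple embeddings
    count as a single containment.
    """
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            from .chem_io import StructureParseError

            raise StructureParseError(f"unparseable SMILES: {molecule!r}")
    else:
        mol = molecule
    return mol.HasSubstructMatch(alert.query)


@dataclass
class MatchProfile:
    """Alert ids matched by one molecule, partitioned by predicted activity.

    Input to the decision tree; the two lists are disjoint and sorted by
    alert_id for determinism.
    """

    record_id: str
    matched_hepatotoxic: list[str] = field(default_factory=list)
    matched_non_hepatotoxic: list[str] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return len(self.matched_hepatotoxic)

    @property
    def n_neg(self) -> int:
        return len(self.matched_non_hepatotoxic)


@dataclass
class RuleSet:
    """An ordered collection of structural alerts with unique ids."""

    alerts: list[StructuralAlert]
    name: str = "ruleset"
    version: str = "1"

    def __post_init__(self) -> None:
        if not self.alerts:
            raise ConfigurationError("a RuleSet needs at least one alert")
        ids = [a.alert_id for a in self.alerts]
        if len(ids) != len(set(ids)):
            raise ConfigurationError(f"duplicate alert_ids in {self.name}")
        self._by_id = {a.alert_id: a for a in self.alerts}

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self) -> Iterator[StructuralAlert]:
        return iter(self.alerts)

    def __getitem__(self, alert_id: str) -> StructuralAlert:
        return self._by_id[alert_id]

    def __contains__(self, alert_id: str) -> bool:
        return alert_id in self._by_id

    def subset(self, activity: Activity) -> list[StructuralAlert]:
        return [a for a in self.alerts if a.predicted_activity is activity]

    # -- persistence ---------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "RuleSet":
        """Load a rule file (CSV or JSON, by extension).

        Fields: ``alert_id,pattern,activity,provenance,description,
        occurrences,tp,fp`` (statistics optional).
        """
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"no such rule file: {path}")
        if path.suffix.lower() == ".json":
            rows = json.loads(path.read_text())
        else:
            with open(path, newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
        alerts = []
        for row in rows:
            stats = None
            if row.get("occurrences") not in (None, ""):
                stats = AlertStats(
                    occurrences=int(row["occurrences"]),
                    tp=int(row["tp"]),
                    fp=int(row["fp"]),
                )
            alerts.append(
                StructuralAlert(
                    alert_id=str(row["alert_id"]),
                    pattern_raw=row["pattern"],
                    predicted_activity=Activity(row["activity"]),
                    provenance=row.get("provenance", "statistical"),
                    description=row.get("description", ""),
                    train_stats=stats,
                    pattern_language=row.get("language") or "smarts",
                )
            )
        return cls(alerts, name=name or path.stem)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        rows = []
        for a in self.alerts:
            row = {
                "alert_id": a.alert_id,
                "pattern": a.pattern_normalized,
                "language": a.pattern_language,
                "activity": a.predicted_activity.value,
                "provenance": a.provenance,
                "description": a.description,
                "occurrences": a.train_stats.occurrences if a.train_stats else "",
                "tp": a.train_stats.tp if a.train_stats else "",
                "fp": a.train_stats.fp if a.train_stats else "",
            }
            rows.append(row)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(rows, indent=2))
        else:
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
                writer.writeheader()
                writer.writerows(rows)


def screen(molecule: str | Chem.Mol, rules: RuleSet,
           record_id: str = "") -> MatchProfile:
    """Match one molecule against every alert in a rule set."""
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            from .chem_io import StructureParseError

            raise StructureParseError(f"unparseable SMILES: {molecule!r}")
    else:
        mol = molecule
    profile = MatchProfile(record_id=record_id)
    for alert in rules:
        if mol.HasSubstructMatch(alert.query):
            if alert.predicted_activity is Activity.HEPATOTOXIC:
                profile.matched_hepatotoxic.append(alert.alert_id)
            else:
                profile.matched_non_hepatotoxic.append(alert.alert_id)
    profile.matched_hepatotoxic.sort()
    profile.matched_non_hepatotoxic.sort()
    return profile


# ---------------------------------------------------------------------------
# Bundled manual rule set: 13 expert-derived alerts.
#
# Patterns are stored as printed (typographic spacing and ^*^ wildcards
# included) and normalized at load time.  Statistics are per-compound
# occurrence counts on the 760-compound training set (408 hepatotoxic /
# 352 non-hepatotoxic); for the two non-hepatotoxic alerts the tp column
# plays the TN role.  Control molecules are synthetic constructs chosen to
# exercise each pattern under RDKit aromaticity perception (see docs).
# ---------------------------------------------------------------------------

_HEP = Activity.HEPATOTOXIC
_NON = Activity.NON_HEPATOTOXIC

_TABLE1_ROWS = [
    # (id, raw SMARTS, activity, description, occ, tp, fp, pos_control, neg_control)
    ("1", "[n,c]1ccn[n,c]c1", _HEP,
     "N-containing aromatic heterocycles (pyridine, pyrazine, pyrimidine)",
     57, 41, 16, "c1ccncc1", "c1ccccc1"),
    ("2", "NS(= O)(= O)c1ccccc1", _HEP,
     "Sulphonamides",
     31, 22, 9, "NS(=O)(=O)c1ccccc1", "CS(N)(=O)=O"),
    ("3", "OC(= O)C1[C,S][S,O,C]C2CC(= O)N12", _HEP,
     "Beta-lactam antibiotics (penicillins)",
     12, 8, 4, "CC1(C)SC2CC(=O)N2C1C(=O)O",
     "CC(=O)NC1C2SCC=C(N2C1=O)C(O)=O"),
    ("4", "O = C1N~CC = C[N,C]1C2C~[S,C]CO2", _HEP,
     "Nucleoside analogs",
     11, 9, 2, "O=C1NCC=CN1C1CCCO1", "c1ccccc1"),
    ("5", "C1[S,C,N,O]c2ccccc2[N,C,S,O]c3ccccc13", _HEP,
     "Tricyclic antidepressants (TCAs)",
     11, 9, 2, "C1Cc2ccccc2Nc2ccccc21", "c1ccc2ccccc2c1"),
    ("6", "[N;!$([N+]);!$(NC = O);!$(N = [N,C,O])][a]", _HEP,
     "Aromatic amines",
     10, 6, 4, "Nc1ccccc1", "CC(=O)Nc1ccccc1"),
    ("7", "O = C1CCCCCCCCCCCCO1", _HEP,
     "Macrolide antibiotics",
     7, 5, 2, "O=C1CCCCCCCCCCCCO1", "O=C1CCCCC1"),
    ("8", "Nc1[n,c]cc2C(= O)C(= CNc2[c,n]1)C(O) = O", _HEP,
     "Anti-bacterial agents (fluoroquinolones)",
     6, 4, 2, "Nc1ccc2C(=O)C(=C[N+](C)(C)c2c1)C(O)=O", "Nc1ccccc1"),
    ("9", "^*^N(^*^)CCC(c1cccc[n,c]1)c2cccc[n,c]2", _HEP,
     "Cationic amphiphilic drugs (CADs)",
     6, 5, 1, "CN(C)CCC(c1ccccc1)c1ccccn1", "CCO"),
    ("10", "CC = C(C)C = CC = C(C)C = C[R,a]", _HEP,
     "Retinoids",
     4, 3, 1, "CC=C(C)C=CC=C(C)C=CC1CCCCC1", "CCCCCC"),
    ("11", "CNC(= O)N(CCCl)N = O", _HEP,
     "Nitrosourea compounds",
     2, 2, 0, "CNC(=O)N(CCCl)N=O", "NC(N)=O"),
    ("12", "C1CC2CCC3C(CC[C,c]4[C,c][C,c][C,c][C,c][C,c]34)C2C1", _NON,
     "Steroids",
     23, 16, 7, "C1CC2CCC3C(CCC4CCCCC34)C2C1", "C1CCC2CCCCC2C1"),
    ("13", "CC(= O)NC1C2[S,O]CC = C(N2C1 = O)C(O) = O", _NON,
     "Beta-lactam antibiotics (cephalosporins)",
     16, 11, 5, "CC(=O)NC1C2SCC=C(N2C1=O)C(O)=O",
     "CC1(C)SC2CC(=O)N2C1C(=O)O"),
]


def load_table1_alerts(check_controls: bool = True) -> RuleSet:
    """The bundled manual rule set: 13 alerts, 11 hepatotoxic.

    With ``check_controls`` every alert is verified against its bundled
    positive- and negative-control molecule; loading fails if any control
    stops matching as expected.
    """
    alerts = [
        StructuralAlert(
            alert_id=aid,
            pattern_raw=raw,
            predicted_activity=activity,
            provenance="manual",
            description=desc,
            train_stats=AlertStats(occurrences=occ, tp=tp, fp=fp),
            positive_control=pos,
            negative_control=neg,
        )
        for aid, raw, activity, desc, occ, tp, fp, pos, neg in _TABLE1_ROWS
    ]
    rules = RuleSet(alerts, name="table1_manual_alerts", version="1")
    if check_controls:
        for alert in rules:
            alert.check_controls()
    return rules
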