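"""Automatic structural-alert extraction from a labeled training set.

Rule induction of the "IF fragment THEN activity" kind: training
molecules are exhaustively fragmented, every distinct fragment is scored
against the training labels (support in each class, likelihood ratio,
percentage of correctly-matched compounds), and a compact rule set is
selected by greedy sequential covering.

Fragmentation cuts acyclic single bonds only, so rings are never broken:
ring systems (and atoms joined by non-single acyclic bonds) are contracted
into block nodes, the remaining bonds form a tree, and every connected
subtree within the configured heavy-atom window is a fragment.  Fragments
are stored as canonical SMILES and matched back as hydrogen-agnostic
substructure queries, so a fragment always matches every molecule it was
cut from.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from rdkit import Chem

from .chem_io import Activity, LabeledDataset, ParameterError
from .alert_engine import (
    AlertStats,
    RuleSet,
    StructuralAlert,
    compile_smiles_query,
)
from .evaluation import likelihood_ratio

__all__ = [
    "MinerConfig",
    "FragmentCandidate",
    "enumerate_fragments",
    "validate_fragment",
    "select_rules",
    "prune_against_manual",
    "mine",
]

#: (min_support, lr_min) presets; artifact defaults for the miner's
#: max / optimal / min extraction settings (permissive -> strict).
MODE_PRESETS = {
    "max": (3, None),
    "optimal": (5, 2.0),
    "min": (8, 5.0),
}


@dataclass
class MinerConfig:
    """Fragment-size window, retention thresholds and selection mode.

    ``min_tp_pct`` is the retention threshold on the percentage of
    correctly-matched training compounds (default 70, applied to both
    activity labels symmetrically).  ``min_support`` / ``lr_min`` default
    from ``mode`` when left unset.
    """

    min_atoms: int = 2
    max_atoms: int = 18
    min_tp_pct: float = 70.0
    mode: str = "optimal"
    min_support: Optional[int] = None
    lr_min: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_atoms > self.max_atoms:
            raise ParameterError("min_atoms must be <= max_atoms")
        if self.min_atoms < 1:
            raise ParameterError("min_atoms must be >= 1")
        if not 50.0 < self.min_tp_pct <= 100.0:
            raise ParameterError("min_tp_pct must be in (50, 100]")
        if self.mode not in MODE_PRESETS:
            raise ParameterError(
                f"mode must be one of {sorted(MODE_PRESETS)}, got {self.mode!r}"
            )
        preset_support, preset_lr = MODE_PRESETS[self.mode]
        if self.min_support is None:
            self.min_support = preset_support
        if self.lr_min is None:
            self.lr_min = preset_lr


@dataclass
class FragmentCandidate:
    """A validated fragment: support counts, label, LR and TP%.

    ``matched_pos`` / ``matched_neg`` record which training molecules the
    fragment embeds in; ``tp_pct`` reads as TN% for non-hepatotoxic
    candidates.
    """

    fragment: str
    n_atoms: int
    support_pos: int
    support_neg: int
    lr: float
    tp_pct: float
    label: Activity
    matched_pos: frozenset[str] = frozenset()
    matched_neg: frozenset[str] = frozenset()

    @property
    def support(self) -> int:
        """Correctly-matched training molecules (the rule's own class)."""
        return (
            self.support_pos
            if self.label is Activity.HEPATOTOXIC
            else self.support_neg
        )

    @property
    def coverage(self) -> frozenset[str]:
        return (
            self.matched_pos
            if self.label is Activity.HEPATOTOXIC
            else self.matched_neg
        )


# -- fragment enumeration ---------------------------------------------------


def _condensed_tree(mol: Chem.Mol) -> tuple[list[list[int]], list[list[int]]]:
    """Contract uncuttable bonds; return (node atom lists, adjacency).

    Cuttable bonds are acyclic single bonds; everything else (ring bonds,
    acyclic multiple bonds) merges its endpoints into one block node.  The
    block graph is acyclic by construction.
    """
    n = mol.GetNumAtoms()
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    cuttable = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.IsInRing()
        ):
            cuttable.append((a, b))
        else:
            union(a, b)

    roots = sorted({find(i) for i in range(n)})
    index = {r: k for k, r in enumerate(roots)}
    nodes: list[list[int]] = [[] for _ in roots]
    for i in range(n):
        nodes[index[find(i)]].append(i)
    adj: list[list[int]] = [[] for _ in roots]
    for a, b in cuttable:
        u, v = index[find(a)], index[find(b)]
        adj[u].append(v)
        adj[v].append(u)
    return nodes, adj


def _connected_subtrees(adj: list[list[int]], sizes: list[int],
                        max_atoms: int):
    """Yield every connected node subset (as a frozenset) once.

    Standard rooted enumeration: subsets containing node ``v`` use only
    nodes >= v, so each subset is generated exactly at its minimum node.
    Extension stops when the atom total exceeds ``max_atoms``.
    """
    n = len(adj)
    for root in range(n):
        if sizes[root] > max_atoms:
            continue
        # frontier: neighbors >= root not yet in the subset
        def extend(subset: frozenset[int], atom_count: int,
                   candidates: list[int], banned: frozenset[int]):
            yield subset, atom_count
            for i, c in enumerate(candidates):
                new_count = atom_count + sizes[c]
                if new_count > max_atoms:
                    continue
                new_banned = banned | frozenset(candidates[:i + 1])
                new_candidates = candidates[i + 1:] + [
                    x
                    for x in adj[c]
                    if x > root and x not in subset and x not in new_banned
                ]
                yield from extend(
                    subset | {c}, new_count, new_candidates, new_banned
                )

        yield from extend(
            frozenset([root]),
            sizes[root],
            [x for x in adj[root] if x > root],
            frozenset(),
        )


def enumerate_fragments(
    molecule: str | Chem.Mol, config: MinerConfig
) -> set[str]:
    """All connected fragments of a molecule within the atom window.

    Fragments are reachable by cutting acyclic single bonds (rings stay
    intact) and are returned as canonical SMILES.  Every fragment matches
    back into the input molecule as a substructure query.
    """
    mol = (
        Chem.MolFromSmiles(molecule) if isinstance(molecule, str) else molecule
    )
    if mol is None:
        from .chem_io import StructureParseError

        raise StructureParseError(f"unparseable SMILES: {molecule!r}")
    nodes, adj = _condensed_tree(mol)
    sizes = [len(block) for block in nodes]
    fragments: set[str] = set()
    for subset, atom_count in _connected_subtrees(
        adj, sizes, config.max_atoms
    ):
        if atom_count < config.min_atoms:
            continue
        atoms = sorted(a for k in subset for a in nodes[k])
        smiles = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms,
                                          canonical=True)
        # re-canonicalize through a parse so identical fragments from
        # different molecules collapse to one key
        frag = Chem.MolFromSmiles(smiles)
        if frag is not None:
            fragments.add(Chem.MolToSmiles(frag))
    return fragments


# -- validation and selection ----------------------------------------------


@lru_cache(maxsize=100_000)
def _parsed(smiles: str) -> Optional[Chem.Mol]:
    """Parse-once cache; validation matches thousands of fragments against
    the same training molecules."""
    return Chem.MolFromSmiles(smiles)


def _fragment_query(fragment: str) -> Chem.Mol:
    """Compile a fragment SMILES as a hydrogen-agnostic substructure query."""
    query = compile_smiles_query(fragment)
    if query is None:
        from .chem_io import StructureParseError

        raise StructureParseError(f"fragment does not parse: {fragment!r}")
    return query


def validate_fragment(
    fragment: str, training: LabeledDataset
) -> Optional[FragmentCandidate]:
    """Score one fragment against the training set.

    Returns None for fragments with zero support.  The candidate's label
    is the class it is enriched in relative to class sizes (ties go to
    hepatotoxic, the conservative side); LR and TP% are computed with that
    class on the TP side.
    """
    query = _fragment_query(fragment)
    pos_ids, neg_ids = [], []
    for r in training:
        mol = _parsed(r.smiles_canonical)
        if mol is not None and mol.HasSubstructMatch(query):
            if r.activity_label is Activity.HEPATOTOXIC:
                pos_ids.append(r.record_id)
            elif r.activity_label is Activity.NON_HEPATOTOXIC:
                neg_ids.append(r.record_id)
    if not pos_ids and not neg_ids:
        return None
    P, N = training.n_positive, training.n_negative
    pos_rate = len(pos_ids) / P if P else 0.0
    neg_rate = len(neg_ids) / N if N else 0.0
    if pos_rate >= neg_rate:
        label = Activity.HEPATOTOXIC
        lr = likelihood_ratio(len(pos_ids), len(neg_ids), P, N)
        tp = len(pos_ids)
    else:
        label = Activity.NON_HEPATOTOXIC
        lr = likelihood_ratio(len(neg_ids), len(pos_ids), N, P)
        tp = len(neg_ids)
    total = len(pos_ids) + len(neg_ids)
    return FragmentCandidate(
        fragment=fragment,
        n_atoms=query.GetNumAtoms(),
        support_pos=len(pos_ids),
        support_neg=len(neg_ids),
        lr=lr,
        tp_pct=100.0 * tp / total,
        label=label,
        matched_pos=frozenset(pos_ids),
        matched_neg=frozenset(neg_ids),
    )


def select_rules(
    candidates: Sequence[FragmentCandidate],
    config: MinerConfig,
    name: str = "mined_rules",
) -> Optional[RuleSet]:
    """Greedy sequential covering over validated candidates.

    Candidates are ranked by LR descending (ties: higher support, smaller
    fragment, lexicographic fragment string) and accepted when they pass
    the TP%/support/LR thresholds and still cover at least one training
    molecule not covered by previously accepted rules of the same label.

    Returns None (with a warning) when nothing survives.
    """
    ranked = sorted(
        candidates,
        key=lambda c: (-c.lr, -c.support, c.n_atoms, c.fragment),
    )
    covered: dict[Activity, set[str]] = {
        Activity.HEPATOTOXIC: set(),
        Activity.NON_HEPATOTOXIC: set(),
    }
    accepted: list[FragmentCandidate] = []
    for cand in ranked:
        if cand.tp_pct < config.min_tp_pct:
            continue
        if cand.support < config.min_support:
            continue
        if config.lr_min is not None and cand.lr < config.lr_min:
            continue
        novel = cand.coverage - covered[cand.label]
        if not novel:
            continue
        covered[cand.label] |= cand.coverage
        accepted.append(cand)

    if not accepted:
        import logging

        logging.getLogger("liversar").warning(
            "rule selection produced an empty rule set"
        )
        return None
    alerts = [
        StructuralAlert(
            alert_id=f"S{k + 1:03d}",
            pattern_raw=c.fragment,
            predicted_activity=c.label,
            provenance="statistical",
            description=f"mined fragment ({c.n_atoms} atoms)",
            pattern_language="smiles",
            train_stats=AlertStats(
                occurrences=c.support_pos + c.support_neg,
                tp=c.support,
                fp=(c.support_neg if c.label is Activity.HEPATOTOXIC
                    else c.support_pos),
            ),
        )
        for k, c in enumerate(accepted)
    ]
    return RuleSet(alerts, name=name)


def _coverage_sets(rules: RuleSet, training: LabeledDataset):
    mols = [(r.record_id, _parsed(r.smiles_canonical)) for r in training]
    out = {}
    for alert in rules:
        out[alert.alert_id] = frozenset(
            rid
            for rid, mol in mols
            if mol is not None and mol.HasSubstructMatch(alert.query)
        )
    return out


def prune_against_manual(
    statistical: RuleSet, manual: RuleSet, training: LabeledDataset
) -> Optional[RuleSet]:
    """Drop statistical alerts made redundant by manual ones.

    A statistical alert is removed when its matched-compound set on the
    training data is identical to, or a subset of, the matched set of a
    manual alert with the same predicted activity.  Alerts with empty
    training coverage are retained (an empty set is vacuously a subset of
    everything, which would otherwise delete every non-matching rule).
    """
    stat_cov = _coverage_sets(statistical, training)
    man_cov = _coverage_sets(manual, training)
    kept = []
    for alert in statistical:
        cov = stat_cov[alert.alert_id]
        redundant = bool(cov) and any(
            cov <= man_cov[m.alert_id]
            for m in manual
            if m.predicted_activity is alert.predicted_activity
        )
        if not redundant:
            kept.append(alert)
    if not kept:
        return None
    return RuleSet(kept, name=statistical.name + "_pruned")


def mine(
    training: LabeledDataset, config: MinerConfig | None = None
) -> Optional[RuleSet]:
    """Full extraction pipeline: fragment, validate, select.

    Deterministic for identical inputs and configuration.
    """
    config = config or MinerConfig()
    fragments: set[str] = set()
    for r in training:
        fragments |= enumerate_fragments(r.smiles_canonical, config)
    candidates = []
    for frag in sorted(fragments):
        cand = validate_fragment(frag, training)
        if cand is not None:
            candidates.append(cand)
    return select_rules(candidates, config)
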