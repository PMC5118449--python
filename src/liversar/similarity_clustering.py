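"""Composite chemical similarity and two-stage clustering.

The similarity index blends a circular fingerprint with three structural-
key descriptors — molecular size, heteroatom profile and functional-group
keys — into a weighted score in [0, 1] that is 1 exactly on identical
structures.  Clustering starts from all-singletons and iteratively moves
compounds to the cluster they are most cohesive with until no improving
move remains; the number of clusters is emergent.  Clusters below an
average-similarity floor are discarded, and surviving clusters are grouped
into super-clusters by single linkage on inter-cluster mean similarity.

The component weights of the original similarity index are not published;
the defaults here (fingerprint 0.6, size 0.15, heteroatom 0.1, functional
groups 0.15) preserve the described architecture and are exposed in
``SimilarityConfig``.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Optional

import networkx as nx
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator, rdFMCS

from .chem_io import (
    LabeledDataset,
    ParameterError,
    StructureParseError,
)

__all__ = [
    "SimilarityConfig",
    "Cluster",
    "ClusterSet",
    "SuperCluster",
    "similarity",
    "cluster",
    "filter_clusters",
    "supercluster",
    "suggest_common_scaffold",
]


@dataclass
class SimilarityConfig:
    """Weights and thresholds of the composite similarity index.

    The four component weights must be non-negative and sum to one.
    ``cohesion_threshold`` is the similarity level at which two compounds
    prefer sharing a cluster over staying apart during the iterative
    refinement (it plays the role of an emergent-K control: higher values
    give more, tighter clusters).
    """

    fingerprint_weight: float = 0.6
    size_weight: float = 0.15
    heteroatom_weight: float = 0.1
    group_weight: float = 0.15
    supercluster_threshold: float = 0.7
    min_avg_similarity: float = 0.7
    cohesion_threshold: float = 0.5

    def __post_init__(self) -> None:
        weights = (
            self.fingerprint_weight,
            self.size_weight,
            self.heteroatom_weight,
            self.group_weight,
        )
        if any(w < 0 for w in weights):
            raise ParameterError("similarity weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ParameterError(
                f"similarity weights must sum to 1, got {sum(weights)}"
            )
        if not 0.0 < self.supercluster_threshold <= 1.0:
            raise ParameterError("supercluster_threshold must be in (0, 1]")


#: Structural keys for the functional-group descriptor: a fixed list of
#: common medicinal-chemistry groups, present/absent per molecule.
FUNCTIONAL_GROUP_SMARTS: tuple[tuple[str, str], ...] = (
    ("hydroxyl", "[OX2H]"),
    ("carboxylic_acid", "C(=O)[OX2H1]"),
    ("ester", "C(=O)O[#6]"),
    ("amide", "C(=O)[NX3]"),
    ("primary_amine", "[NX3;H2;!$(NC=O)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=O)]"),
    ("nitro", "[N+](=O)[O-]"),
    ("nitrile", "C#N"),
    ("sulfonamide", "S(=O)(=O)N"),
    ("sulfone", "S(=O)(=O)[#6]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("halogen", "[F,Cl,Br,I]"),
    ("aromatic_ring", "a1aaaaa1"),
    ("ketone", "[#6]C(=O)[#6]"),
    ("aldehyde", "[CX3H1]=O"),
    ("ether", "[OD2]([#6])[#6]"),
    ("phenol", "[OX2H]c"),
    ("urea", "NC(=O)N"),
    ("lactone", "[C;R](=O)[O;R]"),
)

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=2, fpSize=2048
)
_group_queries = tuple(
    Chem.MolFromSmarts(smarts) for _, smarts in FUNCTIONAL_GROUP_SMARTS
)


@lru_cache(maxsize=8192)
def _features(smiles: str):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"unparseable SMILES: {smiles!r}")
    fp = _fp_generator.GetFingerprint(mol)
    n_heavy = mol.GetNumHeavyAtoms()
    hetero = Counter(
        atom.GetSymbol()
        for atom in mol.GetAtoms()
        if atom.GetSymbol() not in ("C", "H")
    )
    groups = frozenset(
        i for i, q in enumerate(_group_queries) if mol.HasSubstructMatch(q)
    )
    return fp, n_heavy, hetero, groups


def _multiset_tanimoto(a: Counter, b: Counter) -> float:
    if not a and not b:
        return 1.0
    keys = set(a) | set(b)
    inter = sum(min(a[k], b[k]) for k in keys)
    union = sum(max(a[k], b[k]) for k in keys)
    return inter / union


def _set_tanimoto(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def similarity(
    a: str, b: str, config: SimilarityConfig | None = None
) -> float:
    """Composite structural similarity of two SMILES in [0, 1].

    Weighted sum of (i) Morgan-fingerprint Tanimoto, (ii) size agreement
    1 - |nA - nB| / max(nA, nB) over heavy-atom counts, (iii) Tanimoto
    over heteroatom element multisets, (iv) Tanimoto over functional-group
    keys.  Symmetric, and exactly 1 on identical canonical structures.
    """
    config = config or SimilarityConfig()
    fp_a, n_a, het_a, grp_a = _features(a)
    fp_b, n_b, het_b, grp_b = _features(b)
    s_fp = DataStructs.TanimotoSimilarity(fp_a, fp_b)
    s_size = (
        1.0 - abs(n_a - n_b) / max(n_a, n_b) if max(n_a, n_b) > 0 else 1.0
    )
    s_het = _multiset_tanimoto(het_a, het_b)
    s_grp = _set_tanimoto(grp_a, grp_b)
    return (
        config.fingerprint_weight * s_fp
        + config.size_weight * s_size
        + config.heteroatom_weight * s_het
        + config.group_weight * s_grp
    )


@dataclass
class Cluster:
    """A group of compounds; ``avg_similarity`` is the mean pairwise
    similarity over members (1.0 for singletons)."""

    cluster_id: int
    member_ids: list[str]
    avg_similarity: float = 1.0


@dataclass
class ClusterSet:
    """A partition of a dataset into clusters.

    Carries the canonical SMILES of every member and the similarity
    configuration so that filtering and super-clustering can recompute
    inter-molecule similarities, plus the objective trace of the
    refinement iterations (non-decreasing by construction).
    """

    clusters: list[Cluster]
    smiles: dict[str, str] = field(default_factory=dict)
    config: SimilarityConfig = field(default_factory=SimilarityConfig)
    objective_trace: list[float] = field(default_factory=list)
    eliminated: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def member_similarity(self, id_a: str, id_b: str) -> float:
        return similarity(self.smiles[id_a], self.smiles[id_b], self.config)


@dataclass
class SuperCluster:
    supercluster_id: int
    cluster_ids: list[int]


def _avg_pairwise(members: list[str], sim) -> float:
    if len(members) < 2:
        return 1.0
    pairs = list(combinations(members, 2))
    return sum(sim(a, b) for a, b in pairs) / len(pairs)


def cluster(
    ds: LabeledDataset,
    config: SimilarityConfig | None = None,
    seed: int = 0,
) -> ClusterSet:
    """Iterative-refinement clustering with emergent cluster count.

    Every compound starts as its own cluster.  Sweeps (in a seed-shuffled
    order) move each compound to the cluster maximizing its net cohesion
    sum(s_ij - t) over members, with leaving-as-singleton worth 0 and ties
    resolved toward staying, then toward the lowest cluster id.  Each
    applied move strictly increases the global objective
    J = sum over within-cluster pairs of (s_ij - t), so the iteration
    terminates; identical seed and input order reproduce the partition.
    """
    if len(ds) == 0:
        raise ParameterError("cannot cluster an empty dataset")
    config = config or SimilarityConfig()
    t = config.cohesion_threshold
    ids = [r.record_id for r in ds]
    smiles = {r.record_id: r.smiles_canonical for r in ds}
    n = len(ids)
    sim = [[0.0] * n for _ in range(n)]
    for i in range(n):
        sim[i][i] = 1.0
        for j in range(i + 1, n):
            s = similarity(smiles[ids[i]], smiles[ids[j]], config)
            sim[i][j] = sim[j][i] = s

    assignment = list(range(n))  # compound index -> cluster label
    rng = random.Random(seed)
    order = list(range(n))
    rng.shuffle(order)

    def objective() -> float:
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if assignment[i] == assignment[j]:
                    total += sim[i][j] - t
        return total

    trace = [objective()]
    max_sweeps = 200
    for _ in range(max_sweeps):
        moved = False
        for i in order:
            current = assignment[i]
            # net cohesion of i with each existing cluster
            gains: dict[int, float] = {}
            for j in range(n):
                if j == i:
                    continue
                gains[assignment[j]] = (
                    gains.get(assignment[j], 0.0) + sim[i][j] - t
                )
            stay_gain = gains.get(current, 0.0)
            # candidate options: any other cluster, or a fresh singleton
            best_label, best_gain = current, stay_gain
            singleton_label = None
            if stay_gain < 0.0:
                singleton_label = max(assignment) + 1
                best_label, best_gain = singleton_label, 0.0
            for label in sorted(gains):
                if label == current:
                    continue
                if gains[label] > best_gain:
                    best_label, best_gain = label, gains[label]
            if best_label != current and best_gain > stay_gain:
                assignment[i] = best_label
                moved = True
        trace.append(objective())
        if not moved:
            break

    labels = sorted(set(assignment))
    clusters = []
    for k, label in enumerate(labels, start=1):
        members = [ids[i] for i in range(n) if assignment[i] == label]
        clusters.append(
            Cluster(
                cluster_id=k,
                member_ids=members,
                avg_similarity=_avg_pairwise(
                    members,
                    lambda a, b: sim[ids.index(a)][ids.index(b)],
                ),
            )
        )
    return ClusterSet(
        clusters=clusters,
        smiles=smiles,
        config=config,
        objective_trace=trace,
    )


def filter_clusters(
    cs: ClusterSet, min_avg_similarity: float | None = None
) -> ClusterSet:
    """Keep clusters whose average similarity meets the floor.

    Eliminated clusters are reported in ``ClusterSet.eliminated``.
    """
    floor = (
        cs.config.min_avg_similarity
        if min_avg_similarity is None
        else min_avg_similarity
    )
    kept = [c for c in cs.clusters if c.avg_similarity >= floor]
    dropped = [c for c in cs.clusters if c.avg_similarity < floor]
    return ClusterSet(
        clusters=kept,
        smiles=cs.smiles,
        config=cs.config,
        objective_trace=cs.objective_trace,
        eliminated=dropped,
    )


def supercluster(
    cs: ClusterSet, threshold: float | None = None
) -> list[SuperCluster]:
    """Single-linkage grouping of clusters into super-clusters.

    Two clusters link when the mean pairwise similarity between their
    molecules exceeds the threshold; super-clusters are the connected
    components of that graph, so every cluster lands in exactly one.
    """
    thr = (
        cs.config.supercluster_threshold if threshold is None else threshold
    )
    graph = nx.Graph()
    graph.add_nodes_from(c.cluster_id for c in cs.clusters)
    for ca, cb in combinations(cs.clusters, 2):
        inter = [
            cs.member_similarity(a, b)
            for a in ca.member_ids
            for b in cb.member_ids
        ]
        if inter and sum(inter) / len(inter) > thr:
            graph.add_edge(ca.cluster_id, cb.cluster_id)
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)),
        key=lambda comp: comp[0],
    )
    return [
        SuperCluster(supercluster_id=k, cluster_ids=list(comp))
        for k, comp in enumerate(components, start=1)
    ]


def suggest_common_scaffold(
    c: Cluster, ds: LabeledDataset
) -> Optional[str]:
    """Maximum common substructure of a cluster's members, if substantial.

    Returns the member itself for singletons, the MCS (as SMARTS) when it
    has at least 3 heavy atoms, and None otherwise — clusters without an
    unambiguous shared core are left for other approaches.
    """
    mols = [
        Chem.MolFromSmiles(ds[rid].smiles_canonical) for rid in c.member_ids
    ]
    if len(mols) == 1:
        return Chem.MolToSmiles(mols[0])
    result = rdFMCS.FindMCS(
        mols, timeout=10, atomCompare=rdFMCS.AtomCompare.CompareElements
    )
    if result.canceled or result.numAtoms < 3 or not result.smartsString:
        return None
    return result.smartsString
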