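"""Fragment enumeration, validation and rule selection."""

import itertools
import math

import pytest
from rdkit import Chem

import liversar as lv
from liversar.fragment_miner import (
    MinerConfig,
    enumerate_fragments,
    mine,
    prune_against_manual,
    select_rules,
    validate_fragment,
)

H = lv.Activity.HEPATOTOXIC
N = lv.Activity.NON_HEPATOTOXIC


def brute_force_fragments(smiles: str, min_atoms: int,
                          max_atoms: int) -> set[str]:
    """Independent oracle: all connected atom subsets whose boundary
    bonds are exclusively acyclic single bonds."""
    mol = Chem.MolFromSmiles(smiles)
    n = mol.GetNumAtoms()
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
         b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing())
        for b in mol.GetBonds()
    ]
    out: set[str] = set()
    for size in range(min_atoms, min(max_atoms, n) + 1):
        for subset in itertools.combinations(range(n), size):
            chosen = set(subset)
            # connectivity by flood fill over internal bonds
            internal = [(a, b) for a, b, _ in bonds
                        if a in chosen and b in chosen]
            seen = {subset[0]}
            frontier = [subset[0]]
            while frontier:
                cur = frontier.pop()
                for a, b in internal:
                    for x, y in ((a, b), (b, a)):
                        if x == cur and y not in seen:
                            seen.add(y)
                            frontier.append(y)
            if seen != chosen:
                continue
            # every boundary bond must be a cuttable (acyclic single) bond
            boundary_ok = all(
                cuttable
                for a, b, cuttable in bonds
                if (a in chosen) != (b in chosen)
            )
            if not boundary_ok:
                continue
            frag = Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(chosen),
                                            canonical=True)
            reparsed = Chem.MolFromSmiles(frag)
            if reparsed is not None:
                out.add(Chem.MolToSmiles(reparsed))
    return out


class TestEnumerateFragments:
    def test_ethane(self):
        config = MinerConfig(min_atoms=1, max_atoms=2, mode="max")
        assert enumerate_fragments("CC", config) == {"C", "CC"}

    def test_butane_window(self):
        config = MinerConfig(min_atoms=2, max_atoms=3, mode="max")
        assert enumerate_fragments("CCCC", config) == {"CC", "CCC"}

    def test_rings_are_never_broken(self):
        config = MinerConfig(min_atoms=6, max_atoms=6, mode="max")
        assert enumerate_fragments("c1ccccc1", config) == {"c1ccccc1"}
        # nothing smaller than the ring can be produced from benzene
        small = MinerConfig(min_atoms=1, max_atoms=5, mode="max")
        assert enumerate_fragments("c1ccccc1", small) == set()

    @pytest.mark.parametrize(
        "smiles",
        ["CCCC", "CC(C)CO", "c1ccccc1CCO", "COC(C)c1ccncc1",
         "NS(=O)(=O)c1ccccc1"],
    )
    def test_matches_brute_force_oracle(self, smiles):
        config = MinerConfig(min_atoms=1, max_atoms=12, mode="max")
        got = enumerate_fragments(smiles, config)
        expected = brute_force_fragments(smiles, 1, 12)
        assert got == expected

    def test_every_fragment_matches_back(self):
        smiles = "CC(=O)Oc1ccccc1C(=O)O"  # aspirin
        mol = Chem.MolFromSmiles(smiles)
        config = MinerConfig(min_atoms=2, max_atoms=10, mode="max")
        for frag in enumerate_fragments(smiles, config):
            query = Chem.MolFromSmiles(frag)
            assert mol.HasSubstructMatch(query), frag


class TestValidateFragment:
    def test_absent_fragment_is_rejected(self, tiny_dataset):
        assert validate_fragment("CBr", tiny_dataset) is None

    def test_pure_toxicophore_gets_infinite_lr(self):
        ds = lv.dataset_from_smiles(
            [(f"p{i}", "NS(=O)(=O)c1ccccc1", H) for i in range(20)]
            + [(f"n{i}", "CCO", N) for i in range(20)]
        )
        cand = validate_fragment("NS(=O)(=O)c1ccccc1", ds)
        assert cand.lr == math.inf
        assert cand.tp_pct == 100.0
        assert cand.label is H

    def test_balanced_fragment_is_uninformative(self):
        ds = lv.dataset_from_smiles(
            [(f"p{i}", "CCOC", H) for i in range(10)]
            + [(f"n{i}", "CCOC", N) for i in range(10)]
        )
        cand = validate_fragment("CCO", ds)
        assert cand.lr == pytest.approx(1.0)
        assert cand.tp_pct == pytest.approx(50.0)


def _candidate(fragment, pos_ids, neg_ids, P, N_):
    from liversar.fragment_miner import FragmentCandidate

    tp, fp = len(pos_ids), len(neg_ids)
    lr = math.inf if fp == 0 else (tp / fp) * (N_ / P)
    return FragmentCandidate(
        fragment=fragment,
        n_atoms=Chem.MolFromSmiles(fragment).GetNumAtoms(),
        support_pos=tp,
        support_neg=fp,
        lr=lr,
        tp_pct=100.0 * tp / (tp + fp),
        label=H,
        matched_pos=frozenset(pos_ids),
        matched_neg=frozenset(neg_ids),
    )


class TestSelectRules:
    def test_single_good_candidate_is_kept(self):
        cand = _candidate("CCO", [f"p{i}" for i in range(10)], [], 50, 50)
        rules = select_rules([cand], MinerConfig(mode="optimal"))
        assert rules is not None and len(rules) == 1
        assert rules.alerts[0].provenance == "statistical"

    def test_identical_coverage_keeps_exactly_one(self):
        pos = [f"p{i}" for i in range(10)]
        c1 = _candidate("CCO", pos, [], 50, 50)
        c2 = _candidate("CCOC", pos, [], 50, 50)
        rules = select_rules([c1, c2], MinerConfig(mode="optimal"))
        assert len(rules) == 1

    def test_thresholds_are_enforced(self):
        weak = _candidate("CCO", ["p1", "p2"], ["n1"], 50, 50)  # 66% TP
        assert select_rules([weak], MinerConfig(mode="optimal")) is None

    def test_empty_candidate_list_gives_none(self):
        assert select_rules([], MinerConfig()) is None


class TestMine:
    def test_recovers_planted_alert_with_exact_coverage(
        self, sulfonamide_fixture
    ):
        ds, manifest = sulfonamide_fixture
        rules = mine(ds, MinerConfig())
        assert rules is not None
        planted_pos = frozenset(manifest["planted"][0]["realized_pos_ids"])
        covered = []
        for alert in rules.subset(H):
            cov = frozenset(
                r.record_id
                for r in ds
                if r.activity_label is H
                and lv.match(r.smiles_canonical, alert)
            )
            covered.append(cov)
        assert planted_pos in covered

    def test_soundness_every_rule_meets_retention_threshold(
        self, sulfonamide_fixture
    ):
        ds, _ = sulfonamide_fixture
        config = MinerConfig()
        rules = mine(ds, config)
        for alert in rules:
            perf = lv.alert_performance(alert, ds)
            assert perf.occurrences > 0
            assert perf.tp_pct >= config.min_tp_pct

    def test_two_disjoint_toxicophores_both_recovered(self):
        spec = lv.FixtureSpec(
            n_pos=40,
            n_neg=40,
            seed=23,
            planted_alerts=[
                lv.PlantedAlert("NS(=O)(=O)c1ccccc1", 0.5, 0.02),
                lv.PlantedAlert("CNC(=O)N(CCCl)N=O", 0.5, 0.02),
            ],
        )
        ds, manifest = lv.generate(spec)
        rules = mine(ds, MinerConfig(mode="max"))
        for planted in manifest["planted"]:
            pos = frozenset(planted["realized_pos_ids"])
            assert pos, "fixture must realize some carriers"
            recovered = any(
                frozenset(
                    r.record_id
                    for r in ds
                    if r.activity_label is H
                    and lv.match(r.smiles_canonical, alert)
                )
                >= pos
                for alert in rules.subset(H)
            )
            assert recovered, planted["scaffold"]

    def test_determinism(self, sulfonamide_fixture):
        ds, _ = sulfonamide_fixture
        r1 = mine(ds, MinerConfig())
        r2 = mine(ds, MinerConfig())
        assert [a.pattern_normalized for a in r1] == [
            a.pattern_normalized for a in r2
        ]


class TestPruneAgainstManual:
    def test_redundant_statistical_alert_removed(self, table1_rules):
        ds = lv.dataset_from_smiles(
            [(f"p{i}", "NS(=O)(=O)c1ccccc1", H) for i in range(5)]
            + [(f"n{i}", "CCO", N) for i in range(5)]
        )
        stat = lv.RuleSet(
            [
                lv.StructuralAlert(
                    "s1", "NS(=O)(=O)c1ccccc1", H,
                    provenance="statistical", pattern_language="smiles",
                ),
                lv.StructuralAlert(
                    "s2", "CCO", H, provenance="statistical",
                    pattern_language="smiles",
                ),
            ],
            name="stat",
        )
        pruned = prune_against_manual(stat, table1_rules, ds)
        assert "s1" not in pruned          # same compounds as manual alert 2
        assert "s2" in pruned              # disjoint coverage survives

    def test_matches_bitset_oracle_on_random_rules(self, sulfonamide_fixture,
                                                   table1_rules):
        ds, _ = sulfonamide_fixture
        training = lv.LabeledDataset(ds.records[:40])
        fragments = ["NS(=O)(=O)c1ccccc1", "S(=O)=O", "CCO", "c1ccccc1",
                     "CCC", "ClC"]
        stat = lv.RuleSet(
            [
                lv.StructuralAlert(
                    f"s{i}", frag, H, provenance="statistical",
                    pattern_language="smiles",
                )
                for i, frag in enumerate(fragments)
            ],
            name="stat",
        )
        pruned = prune_against_manual(stat, table1_rules, training)

        def coverage(alert):
            return frozenset(
                r.record_id for r in training
                if lv.match(r.smiles_canonical, alert)
            )

        manual_cov = {
            m.alert_id: coverage(m)
            for m in table1_rules
        }
        for alert in stat:
            cov = coverage(alert)
            redundant = bool(cov) and any(
                cov <= manual_cov[m.alert_id]
                for m in table1_rules
                if m.predicted_activity is alert.predicted_activity
            )
            assert (alert.alert_id in pruned) == (not redundant)


class TestMinerConfig:
    def test_mode_presets_resolve(self):
        assert MinerConfig(mode="max").min_support == 3
        assert MinerConfig(mode="optimal").lr_min == 2.0
        assert MinerConfig(mode="min").min_support == 8

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_atoms": 5, "max_atoms": 3},
            {"min_tp_pct": 50.0},
            {"min_tp_pct": 101.0},
            {"mode": "bogus"},
            {"min_atoms": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(lv.ParameterError):
            MinerConfig(**kwargs)
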