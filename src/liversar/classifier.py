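"""Conservative decision tree mapping alert matches to a verdict.

The model deliberately over-calls toxicity: with no matched alert the
compound is left unpredicted ("unknown"); with any matches, the compound
is called non-hepatotoxic only when strictly more non-hepatotoxicity
alerts than hepatotoxicity alerts are found, and hepatotoxic otherwise
(ties included).  Each distinct alert counts once regardless of how many
times it embeds, and manual and statistical alerts carry equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .chem_io import Activity, LabeledDataset
from .alert_engine import MatchProfile, RuleSet, screen

VERDICT_UNKNOWN = "unknown"


@dataclass
class Prediction:
    """Decision-tree verdict for one compound, with its evidence."""

    record_id: str
    n_pos_alerts: int
    n_neg_alerts: int
    verdict: Activity | str
    evidence: MatchProfile


def decide(profile: MatchProfile) -> Prediction:
    """Apply the decision tree to one match profile.

    Truth table: (0, 0) -> unknown; n_neg > n_pos -> non_hepatotoxic;
    otherwise -> hepatotoxic (ties go to the toxic verdict).
    """
    n_pos, n_neg = profile.n_pos, profile.n_neg
    if n_pos == 0 and n_neg == 0:
        verdict: Activity | str = VERDICT_UNKNOWN
    elif n_neg > n_pos:
        verdict = Activity.NON_HEPATOTOXIC
    else:
        verdict = Activity.HEPATOTOXIC
    return Prediction(
        record_id=profile.record_id,
        n_pos_alerts=n_pos,
        n_neg_alerts=n_neg,
        verdict=verdict,
        evidence=profile,
    )


def predict_dataset(ds: LabeledDataset, rules: RuleSet) -> list[Prediction]:
    """One prediction per record, order-preserving and deterministic."""
    return [
        decide(screen(r.smiles_canonical, rules, record_id=r.record_id))
        for r in ds
    ]


def predictions_to_dataframe(predictions: list[Prediction]) -> pd.DataFrame:
    """Tabulate predictions: id, verdict, counts, matched alert ids."""
    return pd.DataFrame(
        {
            "id": [p.record_id for p in predictions],
            "verdict": [
                p.verdict.value if isinstance(p.verdict, Activity) else p.verdict
                for p in predictions
            ],
            "n_pos": [p.n_pos_alerts for p in predictions],
            "n_neg": [p.n_neg_alerts for p in predictions],
            "matched_alerts": [
                ";".join(
                    p.evidence.matched_hepatotoxic
                    + p.evidence.matched_non_hepatotoxic
                )
                for p in predictions
            ],
        }
    )
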