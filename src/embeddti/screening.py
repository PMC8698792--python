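"""Virtual screening: score a molecule library against one target and rank.

Each candidate SMILES is scored by a trained model against a single target
sequence; the population is sorted by prediction score (descending by
default — higher predicted affinity first — with an ascending option for
score conventions where lower is better) and the top k are returned.
Unparseable SMILES are skipped with a logged warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

from .chem_graphs import SmilesParseError, parse_smiles
from .data_pipeline import AffinityRecord
from .neural_model import TrainState, featurize_record, predict_featurized

__all__ = ["ScreeningResult", "screen_rank"]

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    """Ranked shortlist: (rank, smiles, prediction_score) triples with ranks
    contiguous from 1, sorted per the configured direction."""

    ranking: list[tuple[int, str, float]]
    target_sequence: str
    k: int

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rank", "smiles", "score"])
            for rank, smiles, score in self.ranking:
                writer.writerow([rank, smiles, repr(score)])


def screen_rank(
    smiles_list: list[str],
    target_sequence: str,
    state: TrainState,
    k: int = 10,
    direction: str = "desc",
) -> ScreeningResult:
    """Score every parseable molecule against the target and keep the top k.

    The sort is stable: molecules with tied scores keep their input order.
    ``direction='desc'`` ranks the highest predicted affinity first.
    """
    if direction not in ("desc", "asc"):
        raise ValueError(f"direction must be 'desc' or 'asc', got {direction!r}")
    scored: list[tuple[str, float]] = []
    for smiles in smiles_list:
        try:
            parse_smiles(smiles)
        except SmilesParseError:
            logger.warning("skipping unparseable SMILES: %r", smiles)
            continue
        record = AffinityRecord(drug_smiles=smiles,
                                protein_sequence=target_sequence, affinity=0.0)
        score = predict_featurized(featurize_record(record, state.config), state)
        scored.append((smiles, score))
    if not scored:
        raise ValueError("no parseable molecules to screen")
    ordered = sorted(
        scored,
        key=lambda pair: -pair[1] if direction == "desc" else pair[1],
    )  # Python's sort is stable, so ties keep input order
    top = ordered[: min(k, len(ordered))]
    ranking = [(i + 1, smiles, score) for i, (smiles, score) in enumerate(top)]
    return ScreeningResult(ranking=ranking, target_sequence=target_sequence, k=k)
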