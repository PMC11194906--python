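"""Weighted roll-up of indicator scores into a dataset scorecard.

Each leaf indicator's raw score (in [0, 1]) is multiplied by its absolute
weight; sub-dimension and dimension scores are sums of their children's
weighted scores, and the total is the sum of the four dimension scores —
so a flawless dataset totals the sum of the level-1 weights (~1.000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dataset import EMRDataset, ModelingPlan, ReferenceSchema
from .indicators import IndicatorScore, compute_all_indicators
from .registry import IndexSystem

__all__ = ["ScoreCard", "score_dataset", "rollup", "compare_scorecards"]


@dataclass
class ScoreCard:
    label: str
    system_name: str
    system_hash: str
    raw: dict[str, float]         # leaf node id -> raw score
    weighted: dict[str, float]    # node id (all levels) -> weighted score
    total: float
    warnings: list[str] = field(default_factory=list)

    def dimension_scores(self, system: IndexSystem) -> dict[str, float]:
        return {n.name: self.weighted[n.id] for n in system.level(1)}

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "system": {"name": self.system_name, "hash": self.system_hash},
            "raw": self.raw,
            "weighted": self.weighted,
            "total": self.total,
            "warnings": self.warnings,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreCard":
        d = json.loads(Path(path).read_text())
        return cls(label=d["label"], system_name=d["system"]["name"],
                   system_hash=d["system"]["hash"], raw=d["raw"],
                   weighted=d["weighted"], total=d["total"],
                   warnings=d.get("warnings", []))


def _rollup_scores(system: IndexSystem, raw: dict[str, float],
                   excluded: set[str]) -> tuple[dict[str, float], float]:
    """Weighted scores for every node, bottom-up.

    ``excluded`` leaves (not-evaluable under the "exclude" policy) drop out
    of their sibling group with weight renormalization: the remaining
    siblings' weights are scaled so the group still spans its parent weight.
    """
    weighted: dict[str, float] = {}
    for leaf in system.leaves:
        if leaf.id in excluded:
            continue
        weight = leaf.absolute_weight
        if excluded:
            siblings = system.children(leaf.parent_id)
            live = [s for s in siblings if s.id not in excluded]
            gone = [s for s in siblings if s.id in excluded]
            if gone and live:
                lost = sum(s.absolute_weight for s in gone)
                keep = sum(s.absolute_weight for s in live)
                weight = leaf.absolute_weight * (keep + lost) / keep
        weighted[leaf.id] = raw[leaf.id] * weight
    for level in (2, 1):
        for node in system.level(level):
            weighted[node.id] = sum(
                weighted.get(child.id, 0.0) for child in system.children(node.id)
            )
    total = sum(weighted[n.id] for n in system.level(1))
    return weighted, total


def score_dataset(ds: EMRDataset, schema: ReferenceSchema, plan: ModelingPlan,
                  system: IndexSystem, policy: str = "one") -> ScoreCard:
    """Score every leaf indicator on the dataset and roll up to a total."""
    results: dict[str, IndicatorScore] = compute_all_indicators(
        ds, schema, plan, policy=policy)
    raw: dict[str, float] = {}
    warnings: list[str] = []
    excluded: set[str] = set()
    for leaf in system.leaves:
        score = results.get(leaf.calculator_id)
        if score is None:
            raise KeyError(f"no calculator registered for leaf {leaf.id} "
                           f"({leaf.calculator_id})")
        if not score.evaluable:
            warnings.append(f"{leaf.id} ({leaf.calculator_id}) not evaluable: "
                            f"{score.reason}; policy={policy}")
            if policy == "exclude":
                excluded.add(leaf.id)
                continue
        raw[leaf.id] = float(score.raw)
    weighted, total = _rollup_scores(system, raw, excluded)
    return ScoreCard(label=ds.label, system_name=system.name,
                     system_hash=system.content_hash(), raw=raw,
                     weighted=weighted, total=total, warnings=warnings)


def rollup(first_level_scores: dict[str, float],
           system: IndexSystem | None = None, tolerance: float = 0.002) -> float:
    """Total score from the four dimension scores (their plain sum).

    When a ``system`` is given, each dimension score is checked against its
    weight (a weighted dimension score can never exceed the dimension's
    weight beyond rounding headroom).
    """
    if system is not None:
        by_name = {n.name: n for n in system.level(1)}
        for name, value in first_level_scores.items():
            node = by_name.get(name)
            if node is not None and value > node.absolute_weight + tolerance:
                raise ValueError(
                    f"dimension {name!r} score {value} exceeds its weight "
                    f"{node.absolute_weight} beyond tolerance {tolerance}")
    return float(sum(first_level_scores.values()))


def compare_scorecards(cards: list[ScoreCard],
                       system: IndexSystem | None = None) -> pd.DataFrame:
    """Rank scorecards by total; per-dimension columns when a system is given.

    Ties keep stable input order. Mixing cards scored under different index
    systems is an error (their weighted scores are not comparable).
    """
    if len(cards) < 2:
        raise ValueError("need at least two scorecards to compare")
    hashes = {c.system_hash for c in cards}
    if len(hashes) > 1:
        raise ValueError(f"scorecards span multiple index-system versions: {hashes}")
    rows = []
    for order, card in enumerate(cards):
        row = {"label": card.label, "total": card.total, "_order": order}
        if system is not None:
            row.update(card.dimension_scores(system))
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["total", "_order"], ascending=[False, True],
                        kind="stable").drop(columns="_order")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)
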