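"""Consensus scoring and construction of the modified score tool.

Multi-scorer ratings are aggregated per case: the modal score for each item
(ties broken toward the higher, more severe score and flagged), the median
for domain totals and for the VAS.  Items are carried into the modified tool
only if they classified good or good* in every scoring exercise supplied and
were never degenerate (ICC = 0 with alpha = 0 — features with high nominal
agreement but no case-to-case variability, such as ubiquitous MHC class I
overexpression or near-absent infarction, are excluded on this rule).  The
modified tool's domain totals are plain sums of the retained items'
consensus scores: three 0–2 inflammatory items (range 0–6) and a 0–2 + 0–1 +
0–2 muscle-fibre trio (range 0–5) in the published configuration.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tool import ScoreToolDefinition, default_tool

__all__ = [
    "ExerciseClassification",
    "modal_consensus",
    "select_informative_items",
    "modified_domain_totals",
    "consensus_table",
    "ConsensusAggregator",
]


@dataclass(frozen=True)
class ExerciseClassification:
    """Per-item good/good*/poor classification from one scoring exercise."""

    exercise_id: str
    classes: Mapping[str, str]  # item_id -> good | good_star | poor
    degenerate: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_table(cls, table: pd.DataFrame, exercise_id: str = "") -> "ExerciseClassification":
        """Build from a reliability table with item_id, class, degenerate columns."""
        classes = dict(zip(table["item_id"].astype(str), table["class"].astype(str)))
        degenerate = frozenset(table.loc[table["degenerate"].astype(bool), "item_id"].astype(str))
        return cls(exercise_id=exercise_id, classes=classes, degenerate=degenerate)


def modal_consensus(scores: Iterable[int]) -> int:
    """Most frequent score; ties broken toward the higher (more severe) score."""
    scores = list(scores)
    if not scores:
        raise ValueError("modal_consensus needs at least one score")
    counts = Counter(scores)
    best = max(counts.values())
    return max(s for s, c in counts.items() if c == best)


def _modal_with_tie(scores: Sequence[int]) -> tuple[int, bool]:
    counts = Counter(scores)
    best = max(counts.values())
    tied = [s for s, c in counts.items() if c == best]
    return max(tied), len(tied) > 1


def select_informative_items(
    classifications: Sequence[ExerciseClassification],
    tool: ScoreToolDefinition | None = None,
) -> list[str]:
    """Items classified good or good* in *every* exercise and degenerate in none.

    Returns item ids in tool order; composites (domain totals, VAS) are not
    tool items and never appear.  Raises if any exercise fails to classify a
    tool item.
    """
    if not classifications:
        raise ValueError("at least one exercise classification is required")
    tool = tool or default_tool()
    retained: list[str] = []
    for item_id in tool.item_ids:
        ok = True
        for ex in classifications:
            if item_id not in ex.classes:
                raise ValueError(f"exercise {ex.exercise_id!r} does not classify item {item_id!r}")
            if ex.classes[item_id] not in ("good", "good_star") or item_id in ex.degenerate:
                ok = False
        if ok:
            retained.append(item_id)
    return retained


def modified_domain_totals(
    consensus: Mapping[str, int],
    informative_items: Sequence[str],
    tool: ScoreToolDefinition | None = None,
) -> tuple[int, int]:
    """(inflammatory_total, muscle_fibre_total) of the modified tool.

    Each total is the unweighted sum of the case's consensus scores over the
    informative items of that domain.  Raises if a constituent is missing
    from ``consensus``.
    """
    tool = tool or default_tool()
    totals = {"inflammatory": 0, "muscle_fibre": 0}
    for item_id in informative_items:
        domain = tool.item(item_id).domain
        if domain not in totals:
            continue
        if item_id not in consensus:
            raise ValueError(f"consensus scores missing informative item {item_id!r}")
        totals[domain] += int(consensus[item_id])
    return totals["inflammatory"], totals["muscle_fibre"]


def modified_range_maxima(
    informative_items: Sequence[str], tool: ScoreToolDefinition | None = None
) -> tuple[int, int]:
    """Maximum possible (inflammatory, muscle_fibre) modified totals."""
    tool = tool or default_tool()
    maxima = {"inflammatory": 0, "muscle_fibre": 0}
    for item_id in informative_items:
        it = tool.item(item_id)
        if it.domain in maxima:
            maxima[it.domain] += it.max_level
    return maxima["inflammatory"], maxima["muscle_fibre"]


def consensus_table(
    scores: pd.DataFrame,
    vas: pd.DataFrame | None = None,
    tool: ScoreToolDefinition | None = None,
    informative_items: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-case consensus from long scores (scorer_id, case_id, item_id, score).

    One row per case: modal consensus per item, a ``<item>_tie`` flag for
    ties, per-domain medians of the item consensus scores, median VAS (when
    supplied), and — when ``informative_items`` is given — the modified
    inflammatory and muscle-fibre domain totals.
    """
    tool = tool or default_tool()
    rows: dict[str, dict] = {}
    for (case_id, item_id), grp in scores.groupby(["case_id", "item_id"], sort=False):
        mode, tie = _modal_with_tie(grp["score"].astype(int).tolist())
        row = rows.setdefault(str(case_id), {"case_id": str(case_id)})
        row[str(item_id)] = mode
        row[f"{item_id}_tie"] = tie
    out = pd.DataFrame(sorted(rows.values(), key=lambda r: r["case_id"]))

    for domain in ("inflammatory", "vascular", "muscle_fibre", "connective_tissue"):
        cols = [it.item_id for it in tool.items_in_domain(domain) if it.item_id in out.columns]
        if cols:
            out[f"{domain}_domain_median"] = out[cols].median(axis=1)

    if vas is not None and len(vas):
        med = vas.groupby("case_id")["vas"].median()
        out["vas_consensus"] = out["case_id"].map(med)

    if informative_items is not None:
        infl, musc = [], []
        for _, row in out.iterrows():
            i, m = modified_domain_totals(
                {k: row[k] for k in informative_items if k in row and pd.notna(row[k])},
                informative_items,
                tool,
            )
            infl.append(i)
            musc.append(m)
        out["modified_inflammatory_total"] = infl
        out["modified_muscle_total"] = musc
    return out


class ConsensusAggregator(BaseEstimator, TransformerMixin):
    """Transformer from long multi-scorer scores to per-case consensus rows.

    ``fit`` records the tool and the informative-item list; ``transform``
    maps a long scores DataFrame (optionally with a parallel VAS frame passed
    at construction time) to the consensus table.
    """

    def __init__(
        self,
        tool: ScoreToolDefinition | None = None,
        informative_items: Sequence[str] | None = None,
    ):
        self.tool = tool
        self.informative_items = informative_items

    def fit(self, X: pd.DataFrame, y=None):
        self.tool_ = self.tool or default_tool()
        self.informative_items_ = (
            list(self.informative_items) if self.informative_items is not None else None
        )
        return self

    def transform(self, X: pd.DataFrame, vas: pd.DataFrame | None = None) -> pd.DataFrame:
        return consensus_table(X, vas=vas, tool=self.tool_, informative_items=self.informative_items_)
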