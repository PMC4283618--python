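"""Packaged reference tables from the published validation study.

Three small fixtures are shipped with the package (no raw scorer-level data
are public, so these group-level summaries are the only in-study inputs):

* ``cohort``      — the 55-case cohort structure (33 quadriceps/UK, 22
  biceps/Brazil) with demographic and complication summaries;
* ``reliability`` — the per-item ICC and scorer-agreement alpha (with 95%
  CIs) from the two 11×11 inter-observer exercises on quadriceps and biceps,
  with the published bold (good/good*) flags and degeneracy markers;
* ``consensus``   — the consensus-score contingency tables for the six
  informative items, the modified domain-total summaries, and the Spearman
  correlations with manual muscle testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .consensus import ExerciseClassification
from .reliability import classify_item

__all__ = ["Fixtures", "load_fixtures", "reference_classifications"]


@dataclass(frozen=True)
class Fixtures:
    cohort: dict
    reliability: pd.DataFrame
    consensus: dict

    @property
    def group_sizes(self) -> tuple[int, int]:
        return (
            int(self.cohort["groups"]["quadriceps"]["n"]),
            int(self.cohort["groups"]["biceps"]["n"]),
        )

    def contingency(self, item_id: str) -> np.ndarray:
        return np.asarray(self.consensus["contingency"][item_id]["counts"], dtype=int)


def _read_text(name: str) -> str:
    return resources.files("myoscore.data").joinpath(name).read_text()


def load_fixtures() -> Fixtures:
    """Load the packaged reference tables."""
    cohort = json.loads(_read_text("cohort_reference.json"))
    consensus = json.loads(_read_text("consensus_reference.json"))
    from io import StringIO

    reliability = pd.read_csv(StringIO(_read_text("reliability_reference.csv")))
    reliability["bold"] = reliability["bold"].astype(bool)
    reliability["degenerate"] = reliability["degenerate"].astype(bool)
    reliability["composite"] = reliability["composite"].astype(bool)
    return Fixtures(cohort=cohort, reliability=reliability, consensus=consensus)


def reference_classifications(fixtures: Fixtures | None = None) -> list[ExerciseClassification]:
    """Good/good*/poor classification of every scored item in the two
    reference inter-observer exercises (quadriceps and biceps), derived from
    the published ICC/alpha values; composites (domain totals, VAS) are left
    out because they are not tool items."""
    fx = fixtures or load_fixtures()
    items = fx.reliability[~fx.reliability["composite"]]
    out = []
    for muscle, grp in items.groupby("muscle", sort=False):
        classes = {
            str(r.row_id): classify_item(float(r.icc), float(r.alpha))
            for r in grp.itertuples(index=False)
        }
        degenerate = frozenset(grp.loc[grp["degenerate"], "row_id"].astype(str))
        out.append(ExerciseClassification(exercise_id=str(muscle), classes=classes, degenerate=degenerate))
    return sorted(out, key=lambda e: e.exercise_id, reverse=True)  # quadriceps first
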