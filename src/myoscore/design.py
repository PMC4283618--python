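"""Scoring-exercise allocation designs.

The validation exercises allocate biopsy cases to scorers so that reading
order and case–scorer pairing are balanced: a full n×n Latin square for the
main inter-observer exercises (every scorer reads every case, each case
occupying each reading position exactly once across scorers), a partial
design in which each case is read by k of the available scorers with scorer
loads balanced to within one case, and an 8×8 square for the intra-observer
repeat.  Construction is a cyclic square followed by seeded row, column and
symbol permutations, so designs are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DesignAllocation", "latin_square", "partial_latin_square", "check_design"]


@dataclass(frozen=True)
class DesignAllocation:
    """A set of (case_id, scorer_id, position) reading assignments."""

    n_cases: int
    n_scorers: int
    entries: tuple[tuple[str, str, int], ...]
    case_ids: tuple[str, ...] = field(default_factory=tuple)
    scorer_ids: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["case_id", "scorer_id", "position"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DesignAllocation":
        cases = tuple(pd.unique(df["case_id"].astype(str)))
        scorers = tuple(pd.unique(df["scorer_id"].astype(str)))
        entries = tuple(
            (str(r.case_id), str(r.scorer_id), int(r.position))
            for r in df.itertuples(index=False)
        )
        return cls(len(cases), len(scorers), entries, cases, scorers)


def _default_ids(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i + 1:02d}" for i in range(n))


def latin_square(
    n: int,
    seed: int,
    case_ids: Sequence[str] | None = None,
    scorer_ids: Sequence[str] | None = None,
) -> DesignAllocation:
    """Full n×n Latin square: scorer s reads case L[s, p] at position p.

    Each scorer reads every case exactly once, and at each reading position
    every case appears for exactly one scorer.  The square is the cyclic
    square (i + j) mod n with seeded permutations of rows (scorers), columns
    (positions) and symbols (cases).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    case_ids = tuple(case_ids) if case_ids is not None else _default_ids("case", n)
    scorer_ids = tuple(scorer_ids) if scorer_ids is not None else _default_ids("scorer", n)
    if len(case_ids) != n or len(scorer_ids) != n:
        raise ValueError("case_ids and scorer_ids must both have length n")

    rng = np.random.default_rng(seed)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows = rng.permutation(n)
    cols = rng.permutation(n)
    syms = rng.permutation(n)
    square = syms[base[np.ix_(rows, cols)]]

    entries = tuple(
        (case_ids[square[s, p]], scorer_ids[s], p + 1)
        for s in range(n)
        for p in range(n)
    )
    return DesignAllocation(n, n, entries, case_ids, scorer_ids)


def partial_latin_square(
    n_cases: int,
    k: int,
    seed: int,
    case_ids: Sequence[str] | None = None,
    scorer_ids: Sequence[str] | None = None,
    n_scorers: int | None = None,
) -> DesignAllocation:
    """Partial design: each case is read by exactly k scorers from the roster.

    Scorer loads are balanced to within one case by dealing scorers from a
    seeded cyclic order; each scorer's reading positions are a seeded
    permutation 1..load.  With k equal to the roster size the support equals a
    full crossed design.
    """
    if n_cases < 1:
        raise ValueError(f"n_cases must be >= 1, got {n_cases}")
    if scorer_ids is None:
        scorer_ids = _default_ids("scorer", n_scorers if n_scorers is not None else n_cases)
    scorer_ids = tuple(scorer_ids)
    m = len(scorer_ids)
    if k < 1 or k > m:
        raise ValueError(f"k must be between 1 and the roster size {m}, got {k}")
    case_ids = tuple(case_ids) if case_ids is not None else _default_ids("case", n_cases)
    if len(case_ids) != n_cases:
        raise ValueError("case_ids must have length n_cases")

    rng = np.random.default_rng(seed)
    order = rng.permutation(m)  # cyclic dealing order of scorers
    assigned: dict[str, list[str]] = {sid: [] for sid in scorer_ids}
    slot = 0
    for cid in case_ids:
        for _ in range(k):
            sid = scorer_ids[order[slot % m]]
            assigned[sid].append(cid)
            slot += 1
    entries: list[tuple[str, str, int]] = []
    for sid in scorer_ids:
        cases = assigned[sid]
        perm = rng.permutation(len(cases))
        for pos, idx in enumerate(perm, start=1):
            entries.append((cases[idx], sid, pos))
    return DesignAllocation(n_cases, m, tuple(entries), case_ids, scorer_ids)


def check_design(d: DesignAllocation, kind: str = "full") -> list[str]:
    """Report violated design properties (empty list = valid).

    ``kind='full'`` additionally checks the Latin property (each case appears
    at each position for exactly one scorer); ``kind='partial'`` checks equal
    per-case coverage and scorer-load balance to within one.
    """
    if kind not in ("full", "partial"):
        raise ValueError(f"kind must be 'full' or 'partial', got {kind!r}")
    report: list[str] = []
    df = d.to_frame()
    dup = df.duplicated(subset=["case_id", "scorer_id"])
    if dup.any():
        pairs = df.loc[dup, ["case_id", "scorer_id"]].apply(tuple, axis=1).tolist()
        report.append(f"duplicate (case, scorer) pairs: {sorted(set(pairs))}")
    for sid, grp in df.groupby("scorer_id"):
        pos = sorted(grp["position"].tolist())
        if pos != list(range(1, len(pos) + 1)):
            report.append(f"scorer {sid}: positions {pos} are not 1..{len(pos)}")

    if kind == "full":
        n = d.n_cases
        if len(df) != n * d.n_scorers:
            report.append(f"expected {n * d.n_scorers} entries, found {len(df)}")
        for cid, grp in df.groupby("case_id"):
            if len(grp) != d.n_scorers:
                report.append(f"case {cid} read {len(grp)} times, expected {d.n_scorers}")
        latin = df.groupby(["case_id", "position"]).size()
        bad = latin[latin != 1]
        if len(bad):
            report.append(
                f"Latin property violated at (case, position): {sorted(bad.index.tolist())}"
            )
    else:
        per_case = df.groupby("case_id").size()
        if per_case.nunique() > 1:
            report.append(f"unequal per-case coverage: {sorted(per_case.unique().tolist())}")
        loads = df.groupby("scorer_id").size().reindex(list(d.scorer_ids), fill_value=0)
        if loads.max() - loads.min() > 1:
            report.append(
                f"scorer loads unbalanced by more than 1: min {loads.min()}, max {loads.max()}"
            )
    return report
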