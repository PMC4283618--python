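"""Data model for the JDM muscle-biopsy score tool.

The instrument is a set of ordinal histopathology items organised into four
domains — inflammatory, vascular, muscle fibre and connective tissue — plus a
continuous Visual Analogue Score (VAS) for overall severity.  Each item is
scored on a small ordinal scale (0–2 for most items, 0–1 for rare/binary
features such as infarction and neonatal myosin).  This module defines the
validated record types for the tool itself, for biopsy cases with their
clinical data, and for one scorer's completed score sheet, together with
JSON/CSV round-tripping.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

Domain = Literal["inflammatory", "vascular", "muscle_fibre", "connective_tissue"]
DOMAINS: tuple[str, ...] = ("inflammatory", "vascular", "muscle_fibre", "connective_tissue")

__all__ = [
    "Domain",
    "DOMAINS",
    "ScoreItem",
    "ScoreToolDefinition",
    "ClinicalRecord",
    "BiopsyCase",
    "ScoreSheet",
    "ToolValidationError",
    "load_tool_definition",
    "default_tool",
    "validate_score_sheet",
]


class ToolValidationError(ValueError):
    """Raised when a tool definition or score sheet violates the schema."""


class ScoreItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str = Field(min_length=1)
    domain: Domain
    levels: tuple[int, ...]
    label: str = ""

    @field_validator("levels", mode="before")
    @classmethod
    def _coerce_levels(cls, v):
        return tuple(v)

    @field_validator("levels")
    @classmethod
    def _check_levels(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if len(v) == 0:
            raise ValueError("levels must be non-empty")
        if list(v) != list(range(len(v))):
            raise ValueError(
                f"levels must be consecutive integers starting at 0, got {list(v)}"
            )
        return v

    @property
    def max_level(self) -> int:
        return self.levels[-1]


class ScoreToolDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str = "jdm_biopsy_score_tool"
    version: str = "1.0"
    items: tuple[ScoreItem, ...]
    vas_range: tuple[float, float] = (0.0, 10.0)

    @field_validator("items", mode="before")
    @classmethod
    def _coerce_items(cls, v):
        return tuple(v)

    @model_validator(mode="after")
    def _check(self) -> "ScoreToolDefinition":
        if not self.items:
            raise ValueError("tool must define at least one item")
        ids = [it.item_id for it in self.items]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate item_id(s): {sorted(dup)}")
        present = {it.domain for it in self.items}
        missing = [d for d in DOMAINS if d not in present]
        if missing:
            raise ValueError(f"every domain needs at least one item; missing {missing}")
        lo, hi = self.vas_range
        if not lo < hi:
            raise ValueError(f"vas_range lower bound must be < upper, got {self.vas_range}")
        return self

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def item(self, item_id: str) -> ScoreItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item_id {item_id!r}")

    def items_in_domain(self, domain: str) -> list[ScoreItem]:
        return [it for it in self.items if it.domain == domain]

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "vas": {"min": self.vas_range[0], "max": self.vas_range[1]},
            "items": [
                {"id": it.item_id, "domain": it.domain, "levels": list(it.levels), "label": it.label}
                for it in self.items
            ],
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2))


class ClinicalRecord(BaseModel):
    """Case-level clinical measures at the time of biopsy.

    Missing values are explicit ``None`` and are dropped pairwise by the
    association analyses.  MMT is the 0–5 Medical Research Council grade,
    CMAS 0–53 (higher = stronger), PGA 0.0–10.0 (higher = more active).
    """

    model_config = ConfigDict(frozen=True)

    mmt_knee_extensor: Optional[int] = Field(default=None, ge=0, le=5)
    mmt_elbow_flexion: Optional[int] = Field(default=None, ge=0, le=5)
    cmas: Optional[float] = Field(default=None, ge=0, le=53)
    pga: Optional[float] = Field(default=None, ge=0.0, le=10.0)
    calcinosis: Optional[bool] = None
    skin_ulceration: Optional[bool] = None
    lung: Optional[bool] = None
    cardiac: Optional[bool] = None
    gi: Optional[bool] = None
    age_at_onset_years: Optional[float] = Field(default=None, ge=0)
    age_at_biopsy_years: Optional[float] = Field(default=None, ge=0)
    months_to_biopsy: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_ages(self) -> "ClinicalRecord":
        if (
            self.age_at_onset_years is not None
            and self.age_at_biopsy_years is not None
            and self.age_at_biopsy_years < self.age_at_onset_years
        ):
            raise ValueError("age_at_biopsy_years must be >= age_at_onset_years")
        return self


class BiopsyCase(BaseModel):
    model_config = ConfigDict(frozen=True)

    case_id: str
    muscle_source: Literal["quadriceps", "biceps"]
    cohort: Literal["UK", "Brazil"]
    clinical: ClinicalRecord = ClinicalRecord()


class ScoreSheet(BaseModel):
    """One scorer's ratings of one biopsy case.

    ``session`` is 1 for the main inter-observer exercise and 2 for the
    intra-observer repeat.  ``item_scores`` may cover a declared subset of the
    tool's items; any covered item must be scored within its allowed levels.
    """

    model_config = ConfigDict(frozen=False)

    scorer_id: str
    case_id: str
    session: int = Field(default=1, ge=1)
    item_scores: dict[str, int] = Field(default_factory=dict)
    vas: Optional[float] = None
    tool_version: Optional[str] = None


def validate_score_sheet(sheet: ScoreSheet, tool: ScoreToolDefinition) -> ScoreSheet:
    """Validate a score sheet against a tool definition.

    Returns the sheet annotated with the tool version.  Raises
    :class:`ToolValidationError` naming the offending item/value on any
    unknown item id, out-of-range item score, or out-of-range VAS.
    """
    known = set(tool.item_ids)
    for item_id, score in sheet.item_scores.items():
        if item_id not in known:
            raise ToolValidationError(f"unknown item_id {item_id!r} on sheet "
                                      f"({sheet.scorer_id}, {sheet.case_id})")
        item = tool.item(item_id)
        if score not in item.levels:
            raise ToolValidationError(
                f"score {score} for item {item_id!r} not in allowed levels "
                f"{list(item.levels)} ({sheet.scorer_id}, {sheet.case_id})"
            )
    if sheet.vas is not None:
        lo, hi = tool.vas_range
        if not (lo <= sheet.vas <= hi):
            raise ToolValidationError(
                f"vas {sheet.vas} outside range [{lo}, {hi}] "
                f"({sheet.scorer_id}, {sheet.case_id})"
            )
    sheet.tool_version = tool.version
    return sheet


def _tool_from_json_dict(data: Mapping) -> ScoreToolDefinition:
    try:
        items = [
            ScoreItem(
                item_id=raw["id"],
                domain=raw["domain"],
                levels=raw["levels"],
                label=raw.get("label", ""),
            )
            for raw in data["items"]
        ]
        vas = data.get("vas", {"min": 0.0, "max": 10.0})
        return ScoreToolDefinition(
            name=data.get("name", "score_tool"),
            version=str(data.get("version", "1.0")),
            items=items,
            vas_range=(float(vas["min"]), float(vas["max"])),
        )
    except (KeyError, TypeError) as exc:
        raise ToolValidationError(f"malformed tool definition: {exc}") from exc
    except ValueError as exc:
        raise ToolValidationError(str(exc)) from exc


def load_tool_definition(path: str | Path) -> ScoreToolDefinition:
    """Load and validate a tool definition from its JSON schema."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return _tool_from_json_dict(json.loads(p.read_text()))


def default_tool() -> ScoreToolDefinition:
    """The packaged default instrument: 18 ordinal items in four domains plus
    a 0–10 VAS, reproducing the published item list."""
    text = resources.files("myoscore.data").joinpath("tool_default.json").read_text()
    return _tool_from_json_dict(json.loads(text))


# ---------------------------------------------------------------------------
# CSV round-tripping for long-format score sheets


def sheets_to_frames(sheets: Sequence[ScoreSheet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert score sheets to long-format (scores, vas) DataFrames."""
    score_rows, vas_rows = [], []
    for s in sheets:
        for item_id, score in s.item_scores.items():
            score_rows.append(
                {"scorer_id": s.scorer_id, "case_id": s.case_id, "session": s.session,
                 "item_id": item_id, "score": score}
            )
        if s.vas is not None:
            vas_rows.append(
                {"scorer_id": s.scorer_id, "case_id": s.case_id, "session": s.session,
                 "vas": s.vas}
            )
    scores = pd.DataFrame(score_rows, columns=["scorer_id", "case_id", "session", "item_id", "score"])
    vas = pd.DataFrame(vas_rows, columns=["scorer_id", "case_id", "session", "vas"])
    return scores, vas


def frames_to_sheets(scores: pd.DataFrame, vas: pd.DataFrame | None = None) -> list[ScoreSheet]:
    """Inverse of :func:`sheets_to_frames` (sheet order follows first appearance)."""
    sheets: dict[tuple, ScoreSheet] = {}
    for row in scores.itertuples(index=False):
        key = (str(row.scorer_id), str(row.case_id), int(row.session))
        if key not in sheets:
            sheets[key] = ScoreSheet(scorer_id=key[0], case_id=key[1], session=key[2])
        sheets[key].item_scores[str(row.item_id)] = int(row.score)
    if vas is not None and len(vas):
        for row in vas.itertuples(index=False):
            key = (str(row.scorer_id), str(row.case_id), int(row.session))
            if key not in sheets:
                sheets[key] = ScoreSheet(scorer_id=key[0], case_id=key[1], session=key[2])
            sheets[key].vas = float(row.vas)
    return list(sheets.values())
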