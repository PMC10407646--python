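"""Encounter-level self-harm case definition and exposure phenotyping.

A health-care encounter counts as intentional self-harm when it meets any
of three conditions on the diagnosis codes assigned to that encounter
(same encounter ID, not merely same day):

* **A** — an explicit suicide-attempt / intentional self-harm code;
* **B** — a suicidal-ideation code together with an injury-or-poisoning
  code;
* **C** — an injury-or-poisoning code together with a mental-disorder
  code.

A single code may satisfy both slots of a conjunction if it belongs to
both sets; membership, not code-slot exclusivity, is what the definition
tests.  TBI and PTSD exposure is the presence of at least one matching
code on an encounter dated inside a half-open window ``[start, end)`` —
for cohort use, the five years strictly before the index date, so the
index encounter's own codes never count as exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .codesets import CodeSetRegistry, ICDCode, code_matches

__all__ = [
    "Condition",
    "SelfHarmFlag",
    "ExposureGroup",
    "ExposureStatus",
    "classify_encounter",
    "flag_encounters",
    "first_self_harm",
    "group_from_flags",
    "exposure_in_window",
    "exposure_groups",
]


class Condition(str, Enum):
    A_EXPLICIT = "A_explicit"
    B_IDEATION_PLUS_INJURY = "B_ideation_plus_injury"
    C_INJURY_PLUS_MENTAL = "C_injury_plus_mental"


@dataclass(frozen=True)
class SelfHarmFlag:
    encounter_id: int
    conditions: frozenset[Condition]
    date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a self-harm flag must carry at least one condition")


class ExposureGroup(str, Enum):
    NEITHER = "NEITHER"
    TBI_ONLY = "TBI_ONLY"
    PTSD_ONLY = "PTSD_ONLY"
    COMORBID = "COMORBID"


EXPOSURE_ORDER = [g.value for g in ExposureGroup]


@dataclass(frozen=True)
class ExposureStatus:
    tbi: bool
    ptsd: bool

    @property
    def group(self) -> ExposureGroup:
        return group_from_flags(self.tbi, self.ptsd)


def group_from_flags(tbi: bool, ptsd: bool) -> ExposureGroup:
    if tbi and ptsd:
        return ExposureGroup.COMORBID
    if tbi:
        return ExposureGroup.TBI_ONLY
    if ptsd:
        return ExposureGroup.PTSD_ONLY
    return ExposureGroup.NEITHER


def classify_encounter(
    codes: list[ICDCode],
    registry: CodeSetRegistry,
    encounter_id: int = -1,
    date: pd.Timestamp | None = None,
) -> SelfHarmFlag | None:
    """Apply the three-condition case definition to one encounter's codes."""
    if not codes:
        return None
    explicit = any(code_matches(registry["SELF_HARM_EXPLICIT"], c) for c in codes)
    ideation = any(code_matches(registry["SUICIDAL_IDEATION"], c) for c in codes)
    injury = any(code_matches(registry["INJURY_POISONING"], c) for c in codes)
    mental = any(code_matches(registry["MENTAL_DISORDER"], c) for c in codes)
    conds = set()
    if explicit:
        conds.add(Condition.A_EXPLICIT)
    if ideation and injury:
        conds.add(Condition.B_IDEATION_PLUS_INJURY)
    if injury and mental:
        conds.add(Condition.C_INJURY_PLUS_MENTAL)
    if not conds:
        return None
    return SelfHarmFlag(encounter_id=encounter_id, conditions=frozenset(conds), date=date)


def flag_encounters(
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    registry: CodeSetRegistry,
) -> pd.DataFrame:
    """Flag every self-harm encounter in a diagnosis table (vectorized).

    ``encounters``: columns ``encounter_id, patient_id, date``;
    ``diagnoses``: columns ``encounter_id, code`` (normalized), ``system``.
    Returns the audit table of flagged encounters with columns
    ``encounter_id, patient_id, date, cond_A, cond_B, cond_C``.
    """
    if not len(diagnoses):
        return pd.DataFrame(
            columns=["encounter_id", "patient_id", "date", "cond_A", "cond_B", "cond_C"]
        )
    code_s = diagnoses["code"].astype(str)
    sys_s = diagnoses["system"].astype(str)
    masks = pd.DataFrame(
        {
            "explicit": registry["SELF_HARM_EXPLICIT"].match_frame(code_s, sys_s),
            "ideation": registry["SUICIDAL_IDEATION"].match_frame(code_s, sys_s),
            "injury": registry["INJURY_POISONING"].match_frame(code_s, sys_s),
            "mental": registry["MENTAL_DISORDER"].match_frame(code_s, sys_s),
        }
    )
    any_mask = masks.any(axis=1)
    per_enc = (
        masks[any_mask]
        .groupby(diagnoses.loc[any_mask, "encounter_id"])
        .any()
    )
    flags = pd.DataFrame(
        {
            "cond_A": per_enc["explicit"],
            "cond_B": per_enc["ideation"] & per_enc["injury"],
            "cond_C": per_enc["injury"] & per_enc["mental"],
        }
    )
    flags = flags[flags.any(axis=1)].reset_index()
    out = flags.merge(
        encounters[["encounter_id", "patient_id", "date"]], on="encounter_id", how="left"
    )
    return out[["encounter_id", "patient_id", "date", "cond_A", "cond_B", "cond_C"]]


def first_self_harm(flags: pd.DataFrame) -> pd.DataFrame:
    """First flagged encounter per patient.

    Ties on the same date break to the smallest encounter ID.  Input is
    the audit table from :func:`flag_encounters`; output has columns
    ``patient_id, index_date, encounter_id``.
    """
    if not len(flags):
        return pd.DataFrame(columns=["patient_id", "index_date", "encounter_id"])
    ordered = flags.sort_values(["patient_id", "date", "encounter_id"], kind="mergesort")
    first = ordered.groupby("patient_id", as_index=False).first()
    return first.rename(columns={"date": "index_date"})[
        ["patient_id", "index_date", "encounter_id"]
    ]


def exposure_in_window(
    diagnoses: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    registry: CodeSetRegistry,
) -> ExposureStatus:
    """TBI/PTSD status for one patient over half-open ``[start, end)``.

    ``diagnoses`` needs columns ``date, code, system`` for that patient.
    """
    start, end = window
    if not start < end:
        raise ValueError(f"malformed window: {start} .. {end}")
    if not len(diagnoses):
        return ExposureStatus(tbi=False, ptsd=False)
    dates = pd.to_datetime(diagnoses["date"])
    in_win = (dates >= start) & (dates < end)
    sub = diagnoses[in_win]
    if not len(sub):
        return ExposureStatus(tbi=False, ptsd=False)
    code_s = sub["code"].astype(str)
    sys_s = sub["system"].astype(str)
    tbi = bool(registry["TBI"].match_frame(code_s, sys_s).any())
    ptsd = bool(registry["PTSD"].match_frame(code_s, sys_s).any())
    return ExposureStatus(tbi=tbi, ptsd=ptsd)


def exposure_groups(
    encounters: pd.DataFrame,
    diagnoses: pd.DataFrame,
    index_dates: pd.DataFrame,
    registry: CodeSetRegistry,
    lookback_years: int = 5,
) -> pd.DataFrame:
    """Exposure group per patient over the pre-index lookback (vectorized).

    ``index_dates``: columns ``patient_id, index_date``.  Returns one row
    per patient in ``index_dates``: ``patient_id, tbi, ptsd,
    exposure_group``.
    """
    win = index_dates[["patient_id", "index_date"]].copy()
    win["lb_start"] = win["index_date"] - pd.DateOffset(years=lookback_years)
    dx = diagnoses.merge(
        encounters[["encounter_id", "patient_id", "date"]], on="encounter_id"
    ).merge(win, on="patient_id")
    in_lb = (dx["date"] >= dx["lb_start"]) & (dx["date"] < dx["index_date"])
    dx = dx[in_lb]
    if len(dx):
        code_s = dx["code"].astype(str)
        sys_s = dx["system"].astype(str)
        tbi = registry["TBI"].match_frame(code_s, sys_s)
        ptsd = registry["PTSD"].match_frame(code_s, sys_s)
        per_pat = pd.DataFrame({"tbi": tbi, "ptsd": ptsd}).groupby(dx["patient_id"]).any()
    else:
        per_pat = pd.DataFrame(columns=["tbi", "ptsd"])
    out = win[["patient_id"]].merge(
        per_pat.reset_index(), on="patient_id", how="left"
    )
    out[["tbi", "ptsd"]] = out[["tbi", "ptsd"]].fillna(False).astype(bool)
    out["exposure_group"] = [
        group_from_flags(t, p).value for t, p in zip(out["tbi"], out["ptsd"])
    ]
    return out
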