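"""Charlson Comorbidity Index (CCI) from lookback diagnoses.

Uses a file-driven, Quan-style administrative mapping of ICD-9-CM / ICD-10
prefixes onto the 17 Charlson conditions with the original weights
(1/2/3/6).  Each condition counts at most once regardless of repeat codes,
and the standard severity hierarchies apply: complicated diabetes
supersedes uncomplicated, moderate/severe liver disease supersedes mild,
and metastatic solid tumor supersedes (other) malignancy.  No age points
are added: age enters the downstream models as its own covariate.

Scores are banded low (<5), medium (5-15), high (>15).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .codesets import CodeSet, CodeSetConfigError, System, expand_prefix_field

__all__ = [
    "CCIResult",
    "CharlsonMapping",
    "HIERARCHY",
    "load_charlson_mapping",
    "default_charlson_path",
    "cci_score",
    "cci_band",
    "cci_scores_frame",
]

# (superseded, superseding) pairs: if both present, only the severe one scores
HIERARCHY = (
    ("diabetes_uncomplicated", "diabetes_complicated"),
    ("mild_liver_disease", "moderate_severe_liver_disease"),
    ("malignancy", "metastatic_solid_tumor"),
)

CCI_BAND_ORDER = ("LOW", "MEDIUM", "HIGH")


@dataclass(frozen=True)
class CCIResult:
    score: int
    conditions_hit: frozenset[str]
    band: str


@dataclass(frozen=True)
class CharlsonMapping:
    """Condition -> (weight, prefix CodeSet)."""

    weights: dict[str, int]
    sets: dict[str, CodeSet]
    source: str = "<in-memory>"


def default_charlson_path() -> Path:
    return Path(resources.files("vetharm").joinpath("data/charlson_quan.csv"))


def load_charlson_mapping(path: str | Path | None = None) -> CharlsonMapping:
    """Load a condition/weight/system/prefix CSV (ranges allowed)."""
    path = Path(path) if path is not None else default_charlson_path()
    if not path.exists():
        raise CodeSetConfigError(f"Charlson mapping file not found: {path}")
    weights: dict[str, int] = {}
    entries: dict[str, list[tuple[System, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for i, rec in enumerate(reader, start=2):
            cond = rec["condition"].strip()
            w = int(rec["weight"])
            if cond in weights and weights[cond] != w:
                raise CodeSetConfigError(
                    f"{path}:{i}: condition {cond!r} has conflicting weights"
                )
            weights[cond] = w
            system = System(rec["system"].strip().lower())
            for prefix in expand_prefix_field(rec["prefix"]):
                entries.setdefault(cond, []).append((system, prefix))
    sets = {cond: CodeSet(name=f"cci:{cond}", entries=tuple(e))
            for cond, e in entries.items()}
    return CharlsonMapping(weights=weights, sets=sets, source=str(path))


def cci_band(score: int) -> str:
    """Band a CCI score: <5 low, 5-15 medium, >15 high."""
    if score < 5:
        return "LOW"
    if score <= 15:
        return "MEDIUM"
    return "HIGH"


def cci_score(codes: pd.DataFrame, mapping: CharlsonMapping) -> CCIResult:
    """Score one patient's lookback diagnoses.

    ``codes`` needs columns ``code`` (normalized) and ``system``
    (icd9|icd10).  Empty input scores 0 (band LOW).
    """
    hit: set[str] = set()
    if len(codes):
        code_s = codes["code"].astype(str)
        sys_s = codes["system"].astype(str)
        for cond, cset in mapping.sets.items():
            if cset.match_frame(code_s, sys_s).any():
                hit.add(cond)
    for mild, severe in HIERARCHY:
        if severe in hit:
            hit.discard(mild)
    score = sum(mapping.weights[c] for c in hit)
    return CCIResult(score=score, conditions_hit=frozenset(hit), band=cci_band(score))


def cci_scores_frame(
    diagnoses: pd.DataFrame, mapping: CharlsonMapping
) -> pd.DataFrame:
    """Vectorized CCI over a lookback diagnosis table.

    ``diagnoses`` needs columns ``patient_id, code, system`` (codes
    normalized, already restricted to each patient's lookback window).
    Returns one row per patient: ``patient_id, cci_score, cci_band``.
    Patients absent from ``diagnoses`` simply do not appear (score 0 is
    the caller's default for them).
    """
    if not len(diagnoses):
        return pd.DataFrame(columns=["patient_id", "cci_score", "cci_band"])
    code_s = diagnoses["code"].astype(str)
    sys_s = diagnoses["system"].astype(str)
    per_cond = {}
    for cond, cset in mapping.sets.items():
        mask = cset.match_frame(code_s, sys_s)
        per_cond[cond] = mask.groupby(diagnoses["patient_id"]).any()
    hits = pd.DataFrame(per_cond)
    for mild, severe in HIERARCHY:
        hits[mild] &= ~hits[severe]
    weights = pd.Series(mapping.weights)
    scores = (hits * weights.reindex(hits.columns)).sum(axis=1).astype(int)
    out = scores.rename("cci_score").reset_index()
    out["cci_band"] = out["cci_score"].map(cci_band)
    return out
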