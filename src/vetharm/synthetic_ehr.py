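"""Synthetic administrative-EHR generator (patients / encounters / diagnoses).

Two modes share one record builder:

* **fixture** — exact configured cell counts per utilization stratum x
  TBI/PTSD exposure group x self-harm outcome.  Patient records are
  constructed so the downstream pipeline recovers every configured cell
  with zero error, for any generator or pipeline seed.
* **stochastic** — patient-level outcome draws from a logistic model with
  configured intercept, exposure log-odds, and covariate log-odds, used
  for parameter-recovery simulations.

Construction guarantees (fixture mode).  Cases carry exactly one
self-harm-qualifying encounter, at their designated index date, so their
pipeline index is deterministic; the three qualifying conditions
(explicit code; ideation+injury; injury+mental disorder) rotate across
cases.  Controls are built so that *every* index-eligible encounter the
pipeline might sample yields the same eligibility, stratum, and exposure
classification: LOW controls keep all visits within a <5-year span
ending at the designated index, while MEDIUM/HIGH controls carry their
bulk visit history before the study window start (hence not sampleable)
plus a short in-window tail — which confines MEDIUM/HIGH control index
dates to the first ~4.5 years of the window.  Exposure codes sit on the
two earliest lookback visits, inside the 5-year lookback of the
designated index and of every sampleable alternative; TBI and PTSD codes
never share an encounter (a TBI code is injury-class and a PTSD code is
mental-disorder-class, so co-assignment would itself qualify as
self-harm).  Coding system follows the encounter date: ICD-9-CM before
2015-10-01, ICD-10 after, mirroring the US coding transition.

Yearly visit counts are per-stratum constants (visits/year x 5), chosen
inside the configured utilization bands.  Visits are distinct
(patient, date) pairs; multi-diagnosis encounters emit multiple
diagnosis rows for one encounter row.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .comorbidity import cci_band

__all__ = [
    "GeneratorConfig",
    "LogitParams",
    "CellCount",
    "GenerationError",
    "STRATUM_ORDER",
    "ICD10_TRANSITION",
    "generate",
    "generate_cohort_rows",
    "generate_stochastic_outcomes",
    "table2_cell_counts",
    "write_tables",
]

STRATUM_ORDER = ("LOW", "MEDIUM", "HIGH")
GROUP_ORDER = ("NEITHER", "TBI_ONLY", "PTSD_ONLY", "COMORBID")

ICD10_TRANSITION = pd.Timestamp("2015-10-01")

# one concept per encounter; chosen to never cross phenotype set boundaries
_BENIGN = {"icd9": "V700", "icd10": "Z0000"}
_TBI = {"icd9": "85400", "icd10": "S0650XA"}
_PTSD = {"icd9": "30981", "icd10": "F4310"}
_SELF_HARM = {
    "A": {"icd9": ["E9500"], "icd10": ["X710XXA"]},
    "B": {"icd9": ["V6284", "9594"], "icd10": ["R45851", "S0990XA"]},
    "C": {"icd9": ["9594", "311"], "icd10": ["S0990XA", "F329"]},
}
# Charlson plants per target band: MEDIUM scores 5, HIGH scores 17
_CCI_PLANTS = {
    "MEDIUM": {"icd9": ["585", "162", "496"], "icd10": ["N18", "C34", "J44"]},
    "HIGH": {"icd9": ["196", "042", "5722", "585"],
             "icd10": ["C77", "B20", "K721", "N18"]},
}

_DEFAULT_VISIT_RATES = {"LOW": 4.0, "MEDIUM": 11.0, "HIGH": 20.0}

# category margins emulating the published cohort's overall composition
_DEFAULT_MARGINS: dict[str, dict[str, float]] = {
    "age_band": {"<30": 0.048, "30-44": 0.124, "45-69": 0.496, ">=70": 0.332},
    "sex": {"M": 0.931, "F": 0.069},
    "race": {
        "White": 0.7674, "Black": 0.1585, "Asian": 0.0098,
        "AmericanIndianAlaskaNative": 0.0084,
        "NativeHawaiianPacificIslander": 0.0096, "Other": 0.0463,
    },
    "ethnicity": {"Hispanic": 0.056, "NotHispanic": 0.944},
    "marital_status": {
        "Single": 0.123, "Married": 0.550, "Widowed": 0.078,
        "Divorced": 0.243, "Unknown": 0.006,
    },
    "service_connection": {"none": 0.452, "<50%": 0.202, ">=50%": 0.346},
    "cci_band": {"LOW": 1.0, "MEDIUM": 0.0, "HIGH": 0.0},
}

_DEFAULT_STRATUM_MARGINS = {"LOW": 0.4972, "MEDIUM": 0.2509, "HIGH": 0.2519}
_DEFAULT_EXPOSURE_MARGINS = {
    "NEITHER": 0.8374, "TBI_ONLY": 0.0140, "PTSD_ONLY": 0.1333, "COMORBID": 0.0153,
}

_AGE_RANGES = {"<30": (20, 29), "30-44": (30, 44), "45-69": (45, 69), ">=70": (70, 89)}


class GenerationError(ValueError):
    pass


class CellCount(BaseModel):
    stratum: Literal["LOW", "MEDIUM", "HIGH"]
    exposure_group: Literal["NEITHER", "TBI_ONLY", "PTSD_ONLY", "COMORBID"]
    outcome: int = Field(ge=0, le=1)
    n: int = Field(ge=0)


class LogitParams(BaseModel):
    """Logistic outcome model: logit P = intercept + exposure + covariates."""

    intercept: float = -4.0
    exposure_log_odds: dict[str, float] = Field(default_factory=dict)
    covariate_log_odds: dict[str, dict[str, float]] = Field(default_factory=dict)


class GeneratorConfig(BaseModel):
    window_start: date = date(2008, 1, 1)
    window_end: date = date(2017, 12, 31)
    mode: Literal["fixture", "stochastic"] = "fixture"
    cell_counts: Optional[list[CellCount]] = None
    n_patients: Optional[int] = None
    visit_rate_params: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_VISIT_RATES)
    )
    logit_params: Optional[LogitParams] = None
    covariate_margins: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_MARGINS.items()}
    )
    stratum_margins: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_STRATUM_MARGINS)
    )
    exposure_margins: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_EXPOSURE_MARGINS)
    )
    # per-exposure-group covariate margin overrides; makes covariates
    # exposure-associated, i.e. genuine confounders when they also carry
    # outcome log-odds
    covariate_margins_by_group: dict[str, dict[str, dict[str, float]]] = Field(
        default_factory=dict
    )
    thresholds: tuple[float, float] = (6.6, 15.6)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.window_end <= self.window_start:
            raise GenerationError("window_end must follow window_start")
        if self.mode == "fixture" and not self.cell_counts:
            raise GenerationError("fixture mode requires cell_counts")
        if self.mode == "stochastic":
            if self.logit_params is None:
                raise GenerationError("stochastic mode requires logit_params")
            if not self.n_patients:
                raise GenerationError("stochastic mode requires n_patients")
        for cov, margins in self.covariate_margins.items():
            tot = sum(margins.values())
            if abs(tot - 1.0) > 1e-6:
                raise GenerationError(f"{cov} margins sum to {tot}, not 1")
        for grp, by_cov in self.covariate_margins_by_group.items():
            for cov, margins in by_cov.items():
                tot = sum(margins.values())
                if abs(tot - 1.0) > 1e-6:
                    raise GenerationError(
                        f"{grp}/{cov} margins sum to {tot}, not 1"
                    )
        p50, p75 = self.thresholds
        for s, rate in self.visit_rate_params.items():
            v = round(rate * 5)
            lo_ok = s == "LOW" and 2 <= v and rate <= p50
            med_ok = s == "MEDIUM" and v >= 37 and p50 < rate <= p75
            hi_ok = s == "HIGH" and v >= 82 and rate > p75
            if not (lo_ok or med_ok or hi_ok):
                raise GenerationError(
                    f"visit rate {rate}/yr infeasible for stratum {s} "
                    f"(needs the {s} band at thresholds {self.thresholds}; "
                    "MEDIUM/HIGH also need enough visits for an invariant tail)"
                )
        span_days = (self.window_end - self.window_start).days
        v_max = max(round(r * 5) for r in self.visit_rate_params.values())
        if span_days < v_max + 30:
            raise GenerationError("study window too short for configured visit rates")
        return self


def table2_cell_counts(scale: float = 1.0) -> list[CellCount]:
    """The published stratum x exposure x outcome cells, optionally scaled.

    Scaled counts are rounded half away from zero to integers.
    """
    from importlib import resources

    path = resources.files("vetharm").joinpath("data/published_cells.csv")
    df = pd.read_csv(str(path))
    cells = []
    for row in df.itertuples():
        for outcome, n in ((1, row.selfharm_yes), (0, row.selfharm_no)):
            cells.append(
                CellCount(
                    stratum=row.stratum,
                    exposure_group=row.exposure_group,
                    outcome=outcome,
                    n=int(np.floor(n * scale + 0.5)),
                )
            )
    return cells


def _sample_categorical(
    rng: np.random.Generator, margins: dict[str, float], n: int
) -> np.ndarray:
    levels = np.array(list(margins.keys()))
    probs = np.array(list(margins.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def _truth_skeleton(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient truth rows: stratum, exposure group, covariates, outcome."""
    if config.mode == "fixture":
        parts = []
        for cell in config.cell_counts:
            parts.append(
                pd.DataFrame(
                    {
                        "stratum": cell.stratum,
                        "exposure_group": cell.exposure_group,
                        "outcome": cell.outcome,
                    },
                    index=range(cell.n),
                )
            )
        truth = pd.concat(parts, ignore_index=True)
    else:
        n = config.n_patients
        truth = pd.DataFrame(
            {
                "stratum": _sample_categorical(rng, config.stratum_margins, n),
                "exposure_group": _sample_categorical(rng, config.exposure_margins, n),
            }
        )
    n = len(truth)
    for cov, margins in config.covariate_margins.items():
        truth[cov] = _sample_categorical(rng, margins, n)
    for grp, by_cov in config.covariate_margins_by_group.items():
        mask = (truth["exposure_group"] == grp).to_numpy()
        m = int(mask.sum())
        if not m:
            continue
        for cov, margins in by_cov.items():
            truth.loc[mask, cov] = _sample_categorical(rng, margins, m)
    if config.mode == "stochastic":
        truth["outcome"] = generate_stochastic_outcomes(config, truth, rng)
    truth.insert(0, "patient_id", np.arange(1, n + 1))
    return truth


def generate_stochastic_outcomes(
    config: GeneratorConfig,
    design: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bernoulli outcomes from the configured logistic model.

    ``design`` needs ``exposure_group`` plus any covariate columns named
    in ``logit_params.covariate_log_odds``.
    """
    lp = config.logit_params
    if lp is None:
        raise GenerationError("logit_params required for stochastic outcomes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eta = np.full(len(design), lp.intercept, dtype=float)
    for group, beta in lp.exposure_log_odds.items():
        eta += np.where(design["exposure_group"] == group, beta, 0.0)
    for cov, level_betas in lp.covariate_log_odds.items():
        for level, beta in level_betas.items():
            eta += np.where(design[cov].astype(str) == level, beta, 0.0)
    if not np.all(np.isfinite(eta)):
        raise GenerationError("non-finite logits in stochastic outcome model")
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(design)) < p).astype(int)


def _designated_index_days(
    truth: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator,
    v_of: dict[str, int],
) -> np.ndarray:
    """Designated index date per patient, as days since window start.

    Cases and LOW controls range over the whole window; MEDIUM/HIGH
    controls are confined to the early window so their bulk visit history
    can precede the window start (see module docstring).
    """
    span = (pd.Timestamp(config.window_end) - pd.Timestamp(config.window_start)).days
    n = len(truth)
    t0 = rng.integers(0, span + 1, size=n)
    for s in ("MEDIUM", "HIGH"):
        mask = (~truth["outcome"].astype(bool)) & (truth["stratum"] == s)
        m = int(mask.sum())
        if not m:
            continue
        v = v_of[s]
        hi = 1816 - v  # keeps >=1-day spacing for the pre-window history
        if hi <= 10 or hi > span:
            raise GenerationError(
                f"window too short to place {s} control history before it"
            )
        t0[mask.to_numpy()] = rng.integers(10, hi + 1, size=m)
    return t0


def _visit_offsets(
    truth: pd.DataFrame, t0_days: np.ndarray, v_of: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-encounter (patient row index, offset-days-before-index, role).

    Roles: 0 index visit, 1 first exposure slot, 2 second exposure slot,
    3.. CCI plant slots (3,4,5,6), 9 plain visit.  Offsets are distinct
    per patient; offset 0 is the index encounter.
    """
    idx_parts: list[np.ndarray] = []
    off_parts: list[np.ndarray] = []
    role_parts: list[np.ndarray] = []

    def emit(rows: np.ndarray, offsets: np.ndarray) -> None:
        """offsets: (len(rows), k) descending; roles assigned from the
        earliest (largest-offset) visits."""
        m, k = offsets.shape
        roles = np.full(k, 9, dtype=np.int8)
        roles[0] = 1  # earliest visit: exposure slot 1
        if k > 1:
            roles[1] = 2
        for j in range(min(4, max(k - 2, 0))):
            roles[2 + j] = 3 + j
        idx_parts.append(np.repeat(rows, k))
        off_parts.append(offsets.reshape(-1))
        role_parts.append(np.tile(roles, m))
        # index encounter (offset 0)
        idx_parts.append(rows)
        off_parts.append(np.zeros(m, dtype=np.int64))
        role_parts.append(np.zeros(m, dtype=np.int8))

    is_case = truth["outcome"].astype(bool).to_numpy()
    stratum = truth["stratum"].to_numpy()
    rows_all = np.arange(len(truth))

    for s, v in v_of.items():
        case_rows = rows_all[is_case & (stratum == s)]
        if len(case_rows):
            template = np.unique(np.round(np.linspace(30, 1600, v)).astype(np.int64))[::-1]
            emit(case_rows, np.broadcast_to(template, (len(case_rows), v)))
        ctrl_rows = rows_all[~is_case & (stratum == s)]
        if not len(ctrl_rows):
            continue
        if s == "LOW":
            template = np.unique(np.round(np.linspace(1, 1600, v)).astype(np.int64))[::-1]
            emit(ctrl_rows, np.broadcast_to(template, (len(ctrl_rows), v)))
        else:
            d = t0_days[ctrl_rows].astype(np.int64)
            k = v - 3  # history size; tail of 3 in-window visits
            steps = np.linspace(0.0, 1.0, k)
            hist = np.round(
                (d + 1)[:, None] + (1821 - d - 1)[:, None] * steps[None, :]
            ).astype(np.int64)[:, ::-1]
            tail = np.broadcast_to(np.array([3, 2, 1], dtype=np.int64), (len(d), 3))
            emit(ctrl_rows, np.concatenate([hist, tail], axis=1))

    return (
        np.concatenate(idx_parts),
        np.concatenate(off_parts),
        np.concatenate(role_parts),
    )


def generate(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patients, encounters, diagnoses, truth) tables.

    Deterministic given ``config.seed``.  See the module docstring for
    the structural guarantees.
    """
    rng = np.random.default_rng(config.seed)
    v_of = {s: round(r * 5) for s, r in config.visit_rate_params.items()}
    truth = _truth_skeleton(config, rng)
    n = len(truth)
    if n == 0:
        raise GenerationError("configuration generates zero patients")

    ws = pd.Timestamp(config.window_start)
    t0_days = _designated_index_days(truth, config, rng, v_of)
    truth["index_date"] = ws + pd.to_timedelta(t0_days, unit="D")

    # --- patients table -------------------------------------------------
    age_lo = truth["age_band"].map(lambda b: _AGE_RANGES[b][0]).to_numpy()
    age_hi = truth["age_band"].map(lambda b: _AGE_RANGES[b][1]).to_numpy()
    age = rng.integers(age_lo, age_hi + 1)
    extra_days = rng.integers(0, 360, size=n)
    birth = pd.Series(
        [d - pd.DateOffset(years=int(a)) for d, a in zip(truth["index_date"], age)]
    ) - pd.to_timedelta(extra_days, unit="D")
    sc_pct = np.where(
        truth["service_connection"] == "none",
        np.nan,
        np.where(
            truth["service_connection"] == "<50%",
            rng.integers(1, 5, size=n) * 10,
            rng.integers(5, 11, size=n) * 10,
        ),
    )
    patients = pd.DataFrame(
        {
            "patient_id": truth["patient_id"],
            "birth_date": birth.dt.date.astype(str),
            "sex": truth["sex"],
            "race": truth["race"],
            "ethnicity": truth["ethnicity"],
            "marital_status": truth["marital_status"],
            "service_connection_pct": sc_pct,
        }
    )

    # --- encounters -----------------------------------------------------
    row_idx, offsets, roles = _visit_offsets(truth, t0_days, v_of)
    enc_days = t0_days[row_idx] - offsets
    enc = pd.DataFrame(
        {
            "patient_id": truth["patient_id"].to_numpy()[row_idx],
            "date": ws + pd.to_timedelta(enc_days, unit="D"),
            "role": roles,
            "row_idx": row_idx,
        }
    )
    enc = enc.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    enc["encounter_id"] = np.arange(1, len(enc) + 1)
    is_index = enc["role"] == 0
    setting = np.where(
        is_index & (rng.random(len(enc)) < 0.3), "inpatient", "outpatient"
    )
    encounters = pd.DataFrame(
        {
            "encounter_id": enc["encounter_id"],
            "patient_id": enc["patient_id"],
            "date": enc["date"].dt.date.astype(str),
            "setting": setting,
        }
    )

    # --- diagnoses ------------------------------------------------------
    system = np.where(enc["date"] < ICD10_TRANSITION, "icd9", "icd10")
    group = truth["exposure_group"].to_numpy()[enc["row_idx"]]
    outcome = truth["outcome"].to_numpy()[enc["row_idx"]].astype(bool)
    cci_target = truth["cci_band"].to_numpy()[enc["row_idx"]]

    code = np.where(system == "icd9", _BENIGN["icd9"], _BENIGN["icd10"])
    # exposure plants on the two earliest lookback visits
    slot1, slot2 = enc["role"] == 1, enc["role"] == 2
    has_tbi = np.isin(group, ["TBI_ONLY", "COMORBID"])
    has_ptsd = np.isin(group, ["PTSD_ONLY", "COMORBID"])
    tbi_code = np.where(system == "icd9", _TBI["icd9"], _TBI["icd10"])
    ptsd_code = np.where(system == "icd9", _PTSD["icd9"], _PTSD["icd10"])
    code = np.where(slot1 & has_tbi, tbi_code, code)
    code = np.where(slot1 & ~has_tbi & has_ptsd, ptsd_code, code)
    code = np.where(slot2 & has_tbi & has_ptsd, ptsd_code, code)
    # Charlson plants on the next lookback visits
    for j, band in enumerate(["MEDIUM", "HIGH"], start=0):
        plants9 = _CCI_PLANTS[band]["icd9"]
        plants10 = _CCI_PLANTS[band]["icd10"]
        for k in range(len(plants9)):
            slot = enc["role"] == 3 + k
            tgt = cci_target == band
            code = np.where(
                slot & tgt,
                np.where(system == "icd9", plants9[k], plants10[k]),
                code,
            )

    dx = pd.DataFrame(
        {
            "encounter_id": enc["encounter_id"],
            "code": code,
            "system": system,
        }
    )
    # case index encounters: overwrite with rotating self-harm conditions
    case_index = (enc["role"] == 0) & outcome
    case_enc = enc[case_index]
    cond_cycle = np.array(["A", "B", "C"])[
        np.arange(len(case_enc)) % 3
    ]
    extra_rows = []
    base_codes = []
    for (eid, sys_), cond in zip(
        zip(case_enc["encounter_id"], system[case_index.to_numpy()]), cond_cycle
    ):
        codes = _SELF_HARM[cond][sys_]
        base_codes.append((eid, codes[0], sys_))
        for extra in codes[1:]:
            extra_rows.append((eid, extra, sys_))
    if base_codes:
        repl = pd.DataFrame(base_codes, columns=["encounter_id", "code", "system"])
        dx = dx.set_index("encounter_id")
        dx.loc[repl["encounter_id"], "code"] = repl["code"].to_numpy()
        dx = dx.reset_index()
    if extra_rows:
        dx = pd.concat(
            [dx, pd.DataFrame(extra_rows, columns=["encounter_id", "code", "system"])],
            ignore_index=True,
        )
    dx = dx.sort_values(["encounter_id", "code"], kind="mergesort").reset_index(drop=True)

    truth_out = truth[
        [
            "patient_id", "stratum", "exposure_group", "outcome", "index_date",
            "age_band", "sex", "race", "ethnicity", "marital_status",
            "service_connection", "cci_band",
        ]
    ].copy()
    truth_out["index_date"] = truth_out["index_date"].dt.date.astype(str)
    return patients, encounters, dx, truth_out


def generate_cohort_rows(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fast path: analysis-ready cohort rows without the encounter layer.

    Samples the same per-patient truth (stratum, exposure, covariates,
    logistic outcome) and returns rows shaped like the pipeline's cohort
    table — the input of the stats stage — for simulation studies where
    the encounter-level round trip is not under test.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = _truth_skeleton(config, rng)
    truth["is_case"] = truth["outcome"].astype(bool)
    return truth


def write_tables(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame],
    outdir: str | Path,
    config: GeneratorConfig | None = None,
) -> dict[str, Path]:
    """Write the four delimited tables (+ run manifest) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = ("patients", "encounters", "diagnoses", "truth")
    paths = {}
    for name, df in zip(names, tables):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if config is not None:
        manifest = outdir / "generator_manifest.json"
        manifest.write_text(json.dumps(config.model_dump(mode="json"), indent=2))
        paths["manifest"] = manifest
    return paths
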