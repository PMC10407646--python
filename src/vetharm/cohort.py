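"""Cohort construction: index dates, eligibility, utilization, covariates.

Cases carry the date of their first self-harm-flagged encounter as index
date.  Non-cases get an index date drawn from their own encounter dates,
weighted so the calendar distribution of control index dates matches the
empirical distribution of case index dates (monthly bins by default; a
sampled bin with no usable encounter falls back to the nearest bin that
has one, earlier bin on ties).

Control sampling considers only *index-eligible* encounters: dated inside
the study window and preceded by at least two distinct visit dates in the
prior five years.  Sampling a date that would immediately disqualify the
veteran (who must have two lookback visits to enter the cohort at all)
and then excluding them would thin and distort the matched distribution;
restricting to feasible dates keeps the cohort and the matching intact.

Utilization is the number of distinct visit dates in the 5-year lookback
divided by five, banded at the configured cut points (defaults 6.6 and
15.6 visits/year) or at the eligible cohort's empirical 50th/75th
percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BANDS",
    "RACE_LEVELS",
    "MARITAL_LEVELS",
    "SERVICE_CONNECTION_LEVELS",
    "DEFAULT_THRESHOLDS",
    "IndexAssignmentError",
    "index_eligible_encounters",
    "assign_index_dates",
    "apply_eligibility",
    "compute_utilization",
    "age_band",
    "build_cohort_table",
]

DEFAULT_THRESHOLDS = (6.6, 15.6)

AGE_BANDS = ("<30", "30-44", "45-69", ">=70")
RACE_LEVELS = (
    "White",
    "Black",
    "Asian",
    "AmericanIndianAlaskaNative",
    "NativeHawaiianPacificIslander",
    "Other",
)
MARITAL_LEVELS = ("Single", "Married", "Divorced", "Widowed", "Unknown")
SERVICE_CONNECTION_LEVELS = ("none", "<50%", ">=50%")
ETHNICITY_LEVELS = ("Hispanic", "NotHispanic")


class IndexAssignmentError(ValueError):
    pass


def _distinct_visits(encounters: pd.DataFrame) -> pd.DataFrame:
    """Distinct (patient, date) visit pairs, sorted."""
    v = encounters[["patient_id", "date"]].drop_duplicates()
    return v.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


def _bin_of(dates: pd.Series, window_start: pd.Timestamp, bin_months: int) -> np.ndarray:
    months = (dates.dt.year - window_start.year) * 12 + (
        dates.dt.month - window_start.month
    )
    return (months // bin_months).to_numpy()


def index_eligible_encounters(
    encounters: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    lookback_years: int = 5,
    min_prior_visits: int = 2,
) -> pd.DataFrame:
    """Visit dates usable as a control index date.

    A visit qualifies when it lies in ``[window_start, window_end]`` and
    the patient has at least ``min_prior_visits`` distinct visit dates in
    the half-open 5-year window before it.  Returns columns
    ``patient_id, date``.
    """
    start, end = window
    visits = _distinct_visits(encounters)
    grp = visits.groupby("patient_id")["date"]
    kth_prior = grp.shift(min_prior_visits)
    lb_start = visits["date"] - pd.DateOffset(years=lookback_years)
    ok = (
        (visits["date"] >= start)
        & (visits["date"] <= end)
        & kth_prior.notna()
        & (kth_prior >= lb_start)
    )
    return visits[ok].reset_index(drop=True)


def assign_index_dates(
    case_events: pd.DataFrame,
    encounters: pd.DataFrame,
    window: tuple[pd.Timestamp, pd.Timestamp],
    bin_months: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index dates for every patient: first event for cases, matched
    random encounter for controls.

    ``case_events``: ``patient_id, index_date`` from the phenotyper.
    Returns ``(assignments, exclusions)``; assignments has columns
    ``patient_id, index_date, is_case, source, sampling_bin`` and
    exclusions logs controls with no index-eligible encounter.
    Deterministic given ``seed``.
    """
    start, end = window
    rng = np.random.default_rng(seed)
    case_ids = set(case_events["patient_id"])
    bad_case = case_events[
        (case_events["index_date"] < start) | (case_events["index_date"] > end)
    ]
    if len(bad_case):
        raise IndexAssignmentError(
            f"{len(bad_case)} case index dates fall outside the study window"
        )

    cases = case_events[["patient_id", "index_date"]].copy()
    cases["is_case"] = True
    cases["source"] = "first_event"
    cases["sampling_bin"] = _bin_of(cases["index_date"], start, bin_months)

    cand = index_eligible_encounters(encounters, window)
    cand = cand[~cand["patient_id"].isin(case_ids)]
    all_controls = set(encounters["patient_id"].unique()) - case_ids
    with_cand = set(cand["patient_id"])
    dropped = sorted(all_controls - with_cand)
    exclusions = pd.DataFrame(
        {
            "patient_id": dropped,
            "stage": "assign_index_dates",
            "reason": "no index-eligible encounter in window",
        }
    )
    if len(dropped):
        logger.info("excluded %d controls without an index-eligible encounter", len(dropped))

    cand = cand.copy()
    cand["bin"] = _bin_of(cand["date"], start, bin_months)
    cand = cand.sort_values(["patient_id", "bin", "date"], kind="mergesort")

    if len(cases):
        case_bins, counts = np.unique(
            cases["sampling_bin"].to_numpy(), return_counts=True
        )
        probs = counts / counts.sum()
    else:
        logger.warning("no cases: control index dates sampled uniformly")
        case_bins, probs = None, None

    control_ids: list = []
    control_dates: list = []
    control_bins: list = []
    # per-patient candidate arrays, iterated in sorted id order for determinism
    for pid, sub in cand.groupby("patient_id", sort=True):
        dates = sub["date"].to_numpy()
        bins = sub["bin"].to_numpy()
        ubins = np.unique(bins)
        if case_bins is None:
            pick = rng.integers(len(dates))
            chosen_date, chosen_bin = dates[pick], bins[pick]
        else:
            target = rng.choice(case_bins, p=probs)
            pos = np.searchsorted(ubins, target)
            if pos < len(ubins) and ubins[pos] == target:
                chosen_bin = target
            else:
                lo = ubins[pos - 1] if pos > 0 else None
                hi = ubins[pos] if pos < len(ubins) else None
                if lo is None:
                    chosen_bin = hi
                elif hi is None:
                    chosen_bin = lo
                else:  # nearest; ties -> earlier bin
                    chosen_bin = lo if (target - lo) <= (hi - target) else hi
            in_bin = dates[bins == chosen_bin]
            chosen_date = in_bin[rng.integers(len(in_bin))]
        control_ids.append(pid)
        control_dates.append(chosen_date)
        control_bins.append(chosen_bin)

    controls = pd.DataFrame(
        {
            "patient_id": control_ids,
            "index_date": pd.to_datetime(control_dates),
            "is_case": False,
            "source": "matched_random",
            "sampling_bin": control_bins,
        }
    )
    assignments = pd.concat([cases, controls], ignore_index=True)
    assignments = assignments.sort_values("patient_id", kind="mergesort").reset_index(
        drop=True
    )
    return assignments, exclusions


def apply_eligibility(
    encounters: pd.DataFrame,
    assignments: pd.DataFrame,
    lookback_years: int = 5,
    min_visits: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep veterans with >= ``min_visits`` distinct visit dates in the
    half-open lookback ``[index - 5y, index)``.

    Returns ``(eligible_assignments, exclusions)`` and logs exclusion
    counts.  The lookback visit count is attached as ``lookback_visits``.
    """
    visits = _distinct_visits(encounters)
    merged = visits.merge(
        assignments[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    lb_start = merged["index_date"] - pd.DateOffset(years=lookback_years)
    in_lb = (merged["date"] >= lb_start) & (merged["date"] < merged["index_date"])
    n_lb = (
        merged[in_lb].groupby("patient_id").size().rename("lookback_visits")
    )
    out = assignments.merge(n_lb, on="patient_id", how="left")
    out["lookback_visits"] = out["lookback_visits"].fillna(0).astype(int)
    ok = out["lookback_visits"] >= min_visits
    excluded = out[~ok]
    exclusions = pd.DataFrame(
        {
            "patient_id": excluded["patient_id"],
            "stage": "apply_eligibility",
            "reason": f"fewer than {min_visits} lookback visits",
        }
    )
    if len(excluded):
        logger.info(
            "excluded %d veterans with fewer than %d lookback visits",
            len(excluded), min_visits,
        )
    return out[ok].reset_index(drop=True), exclusions


def compute_utilization(
    eligible: pd.DataFrame,
    thresholds: tuple[float, float] | None = DEFAULT_THRESHOLDS,
    lookback_years: int = 5,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Yearly visit rate and LOW/MEDIUM/HIGH stratum per eligible veteran.

    ``eligible`` is the output of :func:`apply_eligibility` (uses its
    ``lookback_visits``).  ``thresholds=None`` computes the 50th/75th
    percentiles of the eligible cohort's yearly rates ("at or below"
    convention: LOW is rate <= p50).  Returns the augmented frame and the
    thresholds used.
    """
    out = eligible.copy()
    out["yearly_visits"] = out["lookback_visits"] / lookback_years
    if thresholds is None:
        p50, p75 = np.percentile(out["yearly_visits"], [50, 75])
        thresholds = (float(p50), float(p75))
        logger.info("empirical utilization thresholds: %.2f / %.2f", *thresholds)
    p50, p75 = thresholds
    out["stratum"] = np.where(
        out["yearly_visits"] <= p50,
        "LOW",
        np.where(out["yearly_visits"] <= p75, "MEDIUM", "HIGH"),
    )
    return out, thresholds


def age_band(age_years: int) -> str:
    if age_years < 30:
        return "<30"
    if age_years <= 44:
        return "30-44"
    if age_years <= 69:
        return "45-69"
    return ">=70"


def _age_at(index_date: pd.Series, birth_date: pd.Series) -> pd.Series:
    """Completed years of age on the index date."""
    before_birthday = (index_date.dt.month < birth_date.dt.month) | (
        (index_date.dt.month == birth_date.dt.month)
        & (index_date.dt.day < birth_date.dt.day)
    )
    return index_date.dt.year - birth_date.dt.year - before_birthday.astype(int)


def build_cohort_table(
    patients: pd.DataFrame,
    utilization: pd.DataFrame,
    exposure: pd.DataFrame,
    cci: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One analysis-ready row per eligible veteran.

    ``utilization``: eligible assignments with stratum columns;
    ``exposure``: ``patient_id, exposure_group``; ``cci``: optional
    ``patient_id, cci_score, cci_band`` (absent patients score 0).
    Unmappable race routes to Other, missing marital status to Unknown,
    with logged counts.
    """
    rows = utilization.merge(
        patients, on="patient_id", how="left", validate="one_to_one"
    ).merge(exposure[["patient_id", "exposure_group"]], on="patient_id", how="left")
    rows["outcome"] = rows["is_case"].astype(int)

    birth = pd.to_datetime(rows["birth_date"])
    rows["age"] = _age_at(rows["index_date"], birth)
    rows["age_band"] = rows["age"].map(age_band)

    race = rows["race"].astype("string").fillna("Other")
    bad_race = ~race.isin(RACE_LEVELS)
    if bad_race.any():
        logger.info("%d unmappable race values routed to Other", int(bad_race.sum()))
    rows["race"] = race.where(~bad_race, "Other")

    marital = rows["marital_status"].astype("string").fillna("Unknown")
    bad_mar = ~marital.isin(MARITAL_LEVELS)
    if bad_mar.any():
        logger.info("%d unmappable marital values routed to Unknown", int(bad_mar.sum()))
    rows["marital_status"] = marital.where(~bad_mar, "Unknown")

    sc = pd.to_numeric(rows["service_connection_pct"], errors="coerce")
    rows["service_connection"] = np.where(
        sc.isna(), "none", np.where(sc < 50, "<50%", ">=50%")
    )

    if cci is not None and len(cci):
        rows = rows.merge(
            cci[["patient_id", "cci_score", "cci_band"]], on="patient_id", how="left"
        )
        rows["cci_score"] = rows["cci_score"].fillna(0).astype(int)
        rows["cci_band"] = rows["cci_band"].fillna("LOW")
    else:
        rows["cci_score"] = 0
        rows["cci_band"] = "LOW"

    cols = [
        "patient_id",
        "stratum",
        "exposure_group",
        "outcome",
        "age_band",
        "sex",
        "race",
        "ethnicity",
        "marital_status",
        "service_connection",
        "cci_band",
        "cci_score",
        "yearly_visits",
        "index_date",
        "is_case",
    ]
    return rows[cols]
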