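"""Index-date assignment, eligibility, utilization strata, covariate bins."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vetharm.cohort import (
    age_band,
    apply_eligibility,
    assign_index_dates,
    build_cohort_table,
    compute_utilization,
    index_eligible_encounters,
)

WINDOW = (pd.Timestamp("2008-01-01"), pd.Timestamp("2017-12-31"))


def enc_frame(spec):
    """spec: list of (patient_id, [dates])."""
    rows = []
    eid = 0
    for pid, dates in spec:
        for d in dates:
            eid += 1
            rows.append({"encounter_id": eid, "patient_id": pid, "date": d})
    out = pd.DataFrame(rows)
    out["date"] = pd.to_datetime(out["date"])
    return out


def cases_frame(items):
    df = pd.DataFrame(items, columns=["patient_id", "index_date"])
    df["index_date"] = pd.to_datetime(df["index_date"])
    return df


def with_history(dates):
    """Prepend two history visits shortly before the first date given."""
    first = pd.Timestamp(dates[0])
    return [first - pd.Timedelta(days=40), first - pd.Timedelta(days=20)] + list(dates)


class TestAssignIndexDates:
    def test_case_keeps_first_event_date(self):
        enc = enc_frame([(1, with_history(["2012-03-01", "2012-06-01"]))])
        cases = cases_frame([(1, "2012-06-01")])
        out, _ = assign_index_dates(cases, enc, WINDOW, seed=0)
        row = out.set_index("patient_id").loc[1]
        assert row["index_date"] == pd.Timestamp("2012-06-01")
        assert row["is_case"] and row["source"] == "first_event"

    def test_control_forced_into_only_available_month(self):
        enc = enc_frame(
            [
                (1, with_history(["2012-06-10"])),  # case
                (2, with_history(["2012-06-20"])),  # control, same month only
            ]
        )
        cases = cases_frame([(1, "2012-06-10")])
        out, _ = assign_index_dates(cases, enc, WINDOW, seed=1)
        ctrl = out.set_index("patient_id").loc[2]
        assert ctrl["index_date"] == pd.Timestamp("2012-06-20")
        assert not ctrl["is_case"] and ctrl["source"] == "matched_random"

    def test_two_bins_sampled_near_fifty_fifty(self):
        # case index dates split 50/50 across two months; every control can
        # serve either month, so control bins follow the sampling law
        n_ctrl = 4000
        case_list = [(i, "2010-03-15") for i in range(1, 51)] + [
            (i, "2014-09-15") for i in range(51, 101)
        ]
        spec = [(pid, with_history([d])) for pid, d in case_list]
        for j in range(n_ctrl):
            pid = 1000 + j
            spec.append(
                (pid, with_history(["2010-03-10"]) + with_history(["2014-09-10"]))
            )
        enc = enc_frame(spec)
        out, _ = assign_index_dates(cases_frame(case_list), enc, WINDOW, seed=3)
        ctrl = out[~out["is_case"]]
        share = (ctrl["index_date"].dt.year == 2010).mean()
        band = sps.norm.ppf(0.995) * np.sqrt(0.25 / n_ctrl)
        assert abs(share - 0.5) < band

    def test_nearest_bin_fallback_prefers_earlier_on_tie(self):
        # all case mass in June; the control has usable encounters only in
        # September -> fallback lands there
        enc = enc_frame(
            [
                (1, with_history(["2012-06-10"])),
                (2, with_history(["2012-09-05"])),
            ]
        )
        cases = cases_frame([(1, "2012-06-10")])
        out, _ = assign_index_dates(cases, enc, WINDOW, seed=5)
        assert out.set_index("patient_id").loc[2, "index_date"] == pd.Timestamp(
            "2012-09-05"
        )

    def test_control_without_candidates_excluded_with_reason(self):
        enc = enc_frame(
            [
                (1, with_history(["2012-06-10"])),
                (2, ["2012-06-20"]),  # a single visit: no eligible index
            ]
        )
        cases = cases_frame([(1, "2012-06-10")])
        out, excl = assign_index_dates(cases, enc, WINDOW, seed=5)
        assert 2 not in set(out["patient_id"])
        assert excl.set_index("patient_id").loc[2, "stage"] == "assign_index_dates"

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        spec = []
        case_list = []
        for pid in range(1, 40):
            d = pd.Timestamp("2009-01-01") + pd.Timedelta(days=int(rng.integers(0, 2800)))
            case_list.append((pid, d))
            spec.append((pid, with_history([d])))
        for pid in range(100, 400):
            ds = sorted(
                pd.Timestamp("2009-01-01") + pd.Timedelta(days=int(x))
                for x in rng.integers(0, 2800, size=6)
            )
            spec.append((pid, with_history(ds[:1]) + ds[1:]))
        enc = enc_frame(spec)
        a, _ = assign_index_dates(cases_frame(case_list), enc, WINDOW, seed=77)
        b, _ = assign_index_dates(cases_frame(case_list), enc, WINDOW, seed=77)
        pd.testing.assert_frame_equal(a, b)

    def test_matching_improves_with_control_sample_size(self):
        # chi-square distance between control and case monthly distributions
        # shrinks as the control pool grows
        rng = np.random.default_rng(11)
        months = pd.date_range("2009-01-15", "2016-12-15", freq="MS") + pd.Timedelta(days=14)
        case_list = []
        spec = []
        pid = 0
        for m in months:
            for _ in range(3):
                pid += 1
                case_list.append((pid, m))
                spec.append((pid, with_history([m])))
        case_dist = pd.Series([m.to_period("M") for _, m in case_list]).value_counts(
            normalize=True
        )

        def chi2_distance(n_ctrl, seed):
            spec_c = list(spec)
            for j in range(n_ctrl):
                # controls can serve any month: one visit per month
                spec_c.append((10_000 + j, with_history(list(months[:1])) + list(months[1:])))
            enc = enc_frame(spec_c)
            out, _ = assign_index_dates(cases_frame(case_list), enc, WINDOW, seed=seed)
            ctrl = out[~out["is_case"]]
            ctrl_dist = ctrl["index_date"].dt.to_period("M").value_counts(normalize=True)
            joined = pd.concat([case_dist, ctrl_dist], axis=1).fillna(0)
            p, q = joined.iloc[:, 0], joined.iloc[:, 1]
            return float(((p - q) ** 2 / (p + q).replace(0, np.nan)).sum())

        assert chi2_distance(2000, seed=21) < chi2_distance(100, seed=21)


class TestEligibility:
    def test_boundary_rules(self):
        idx = pd.Timestamp("2013-01-01")
        lb = idx - pd.DateOffset(years=5)
        enc = enc_frame(
            [
                (1, [lb, idx - pd.Timedelta(days=10), idx]),  # lb start in, index out
                (2, [idx - pd.Timedelta(days=10), idx, idx + pd.Timedelta(days=5)]),
                (3, [idx - pd.Timedelta(days=400), idx - pd.Timedelta(days=10), idx]),
            ]
        )
        assignments = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "index_date": idx,
                "is_case": [True, True, True],
                "source": "first_event",
                "sampling_bin": 0,
            }
        )
        eligible, excl = apply_eligibility(enc, assignments)
        kept = set(eligible["patient_id"])
        assert kept == {1, 3}  # patient 2 has only 1 pre-index visit
        assert excl.iloc[0]["patient_id"] == 2


class TestUtilization:
    @pytest.mark.parametrize(
        "n_visits,stratum", [(33, "LOW"), (78, "MEDIUM"), (79, "HIGH")]
    )
    def test_default_thresholds(self, n_visits, stratum):
        elig = pd.DataFrame({"patient_id": [1], "lookback_visits": [n_visits]})
        out, used = compute_utilization(elig)
        assert used == (6.6, 15.6)
        assert out.loc[0, "yearly_visits"] == pytest.approx(n_visits / 5)
        assert out.loc[0, "stratum"] == stratum

    def test_empirical_percentiles_split_50_25_25(self, rng):
        elig = pd.DataFrame(
            {
                "patient_id": np.arange(4000),
                "lookback_visits": rng.integers(2, 180, size=4000),
            }
        )
        out, used = compute_utilization(elig, thresholds=None)
        shares = out["stratum"].value_counts(normalize=True)
        assert shares["LOW"] == pytest.approx(0.50, abs=0.03)
        assert shares["MEDIUM"] == pytest.approx(0.25, abs=0.03)
        assert shares["HIGH"] == pytest.approx(0.25, abs=0.03)


class TestCohortTable:
    def test_covariate_binning(self):
        patients = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "birth_date": pd.to_datetime(["1980-01-02", "1950-07-01", "1941-01-01"]),
                "sex": ["M", "F", "M"],
                "race": ["White", "MULTIPLE", "Black"],
                "ethnicity": ["NotHispanic", "Hispanic", "NotHispanic"],
                "marital_status": ["Married", None, "Divorced"],
                "service_connection_pct": [50, np.nan, 20],
            }
        )
        utilization = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "index_date": pd.to_datetime(["2010-01-01", "2010-06-15", "2011-01-01"]),
                "is_case": [True, False, False],
                "lookback_visits": [10, 40, 90],
                "yearly_visits": [2.0, 8.0, 18.0],
                "stratum": ["LOW", "MEDIUM", "HIGH"],
            }
        )
        exposure = pd.DataFrame(
            {"patient_id": [1, 2, 3], "exposure_group": ["NEITHER", "COMORBID", "TBI_ONLY"]}
        )
        out = build_cohort_table(patients, utilization, exposure).set_index("patient_id")
        assert out.loc[1, "age_band"] == "<30"  # turns 30 the next day
        assert out.loc[1, "service_connection"] == ">=50%"
        assert out.loc[2, "marital_status"] == "Unknown"
        assert out.loc[2, "race"] == "Other"
        assert out.loc[3, "service_connection"] == "<50%"
        assert out.loc[2, "cci_band"] == "LOW"  # no CCI table -> score 0
        assert set(out["outcome"]) == {0, 1}


@pytest.mark.parametrize(
    "age,band", [(29, "<30"), (30, "30-44"), (44, "30-44"), (45, "45-69"),
                 (69, "45-69"), (70, ">=70")]
)
def test_age_band_boundaries(age, band):
    assert age_band(age) == band


def test_index_eligible_requires_two_prior_lookback_visits():
    enc = enc_frame(
        [(1, ["2010-01-01", "2010-02-01", "2010-03-01", "2016-06-01"])]
    )
    out = index_eligible_encounters(enc, WINDOW)
    # first two dates lack two priors; 2016 visit is >5y past the early ones
    assert list(out["date"]) == [pd.Timestamp("2010-03-01")]
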