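"""Prevalence, 2x2 odds ratios, and adjusted logistic models.

Bivariable odds ratios use the cross-product estimate with Woolf
(log-normal) confidence intervals; zero cells fall back to the Haldane
continuity correction (+0.5 to every cell) and the estimate is flagged.
Adjusted odds ratios come from maximum-likelihood logistic regression fit
by iteratively reweighted least squares, with Wald intervals
``exp(beta +/- 1.96 * SE)``.  On a saturated single-factor design the two
routes coincide, which the test suite exploits as an analytic oracle.

Reference levels: the unexposed (NEITHER) group for the TBI/PTSD factor,
and the largest observed category for every other covariate; choices are
recorded on the fit result so run manifests can echo them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotype import EXPOSURE_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "Z95",
    "ContingencyTable",
    "OREstimate",
    "ModelSpec",
    "FitResult",
    "MINIMAL_COVARIATES",
    "FULL_COVARIATES",
    "prevalence",
    "round_half_up",
    "odds_ratio",
    "build_design",
    "fit_logistic",
    "stratified_analysis",
]

Z95 = 1.96  # normal quantile used for all 95% intervals

MINIMAL_COVARIATES = ("age_band", "sex", "race")
FULL_COVARIATES = MINIMAL_COVARIATES + (
    "ethnicity",
    "marital_status",
    "service_connection",
    "cci_band",
)


class UndefinedPrevalenceError(ZeroDivisionError):
    pass


class RankDeficientDesignError(ValueError):
    pass


def prevalence(cases: int, noncases: int) -> float:
    """Percentage 100*cases/(cases+noncases), unrounded."""
    total = cases + noncases
    if total <= 0:
        raise UndefinedPrevalenceError("prevalence undefined for an empty cell")
    return 100.0 * cases / total


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for the report layer (11.625 -> 11.63)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a exposed cases, b exposed non-cases, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def swapped(self) -> "ContingencyTable":
        """Exposure labels swapped (OR inverts)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OREstimate:
    or_point: float
    ci_low: float
    ci_high: float
    method: str  # "woolf" | "woolf_haldane" | "wald_logistic"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")


def odds_ratio(t: ContingencyTable) -> OREstimate:
    """Cross-product OR with a Woolf 95% CI.

    Any zero cell triggers the Haldane +0.5 correction, flagged in
    ``method``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    method = "woolf"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_haldane"
        logger.warning("zero cell in 2x2 table %s; Haldane correction applied", t)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(point)
    return OREstimate(
        or_point=point,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        method=method,
    )


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter the logistic model.

    ``adjustment``: ``bivariable`` (exposure only), ``minimal``
    (+ age, sex, race) or ``full`` (+ ethnicity, marital status,
    service-connection, CCI band).
    """

    adjustment: str = "bivariable"

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.adjustment == "bivariable":
            return ()
        if self.adjustment == "minimal":
            return MINIMAL_COVARIATES
        if self.adjustment == "full":
            return FULL_COVARIATES
        raise ValueError(f"unknown adjustment {self.adjustment!r}")


@dataclass
class FitResult:
    params: pd.Series
    bse: pd.Series
    table: pd.DataFrame  # term, coef, se, or, ci_low, ci_high
    reference_levels: dict[str, str]
    converged: bool
    n_iter: int
    score_norm: float
    flags: list[str] = field(default_factory=list)

    def exposure_or(self, group: str) -> OREstimate:
        row = self.table.loc[self.table["term"] == f"exposure_group[{group}]"]
        if not len(row):
            raise KeyError(f"no exposure term for group {group!r}")
        r = row.iloc[0]
        return OREstimate(r["or"], r["ci_low"], r["ci_high"], "wald_logistic")


def build_design(
    rows: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Dummy-coded design matrix with logged reference levels.

    Exposure reference is NEITHER; every other covariate's reference is
    its largest observed category.
    """
    y = rows["outcome"].astype(float)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(rows))}
    refs: dict[str, str] = {"exposure_group": "NEITHER"}
    for grp in EXPOSURE_ORDER:
        if grp == "NEITHER":
            continue
        if (rows["exposure_group"] == grp).any():
            cols[f"exposure_group[{grp}]"] = (
                (rows["exposure_group"] == grp).to_numpy(float)
            )
    for cov in spec.covariates:
        counts = rows[cov].astype(str).value_counts()
        ref = counts.index[0]
        refs[cov] = str(ref)
        for level in sorted(counts.index):
            if level == ref:
                continue
            cols[f"{cov}[{level}]"] = (rows[cov].astype(str) == level).to_numpy(float)
    X = pd.DataFrame(cols, index=rows.index)
    return X, y, refs


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    return [c for c, flag in zip(X.columns, bad) if flag]


def fit_logistic(
    rows: pd.DataFrame,
    spec: ModelSpec,
    *,
    maxiter: int = 50,
    score_tol: float = 1e-8,
    separation_threshold: float = 15.0,
) -> FitResult:
    """ML logistic fit (IRLS) of self-harm outcome on exposure + covariates.

    ``rows`` is the analysis table (one row per veteran) with an integer
    ``outcome`` column.  Requires at least one case and one non-case.
    Non-convergence and quasi-separation (|coefficient| above
    ``separation_threshold``) are flagged, not silently returned; a rank
    deficient design raises naming the collinear columns.
    """
    n_case = int(rows["outcome"].sum())
    if n_case == 0 or n_case == len(rows):
        raise ValueError("logistic fit needs at least one case and one non-case")
    X, y, refs = build_design(rows, spec)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise RankDeficientDesignError(
            "collinear design columns: " + ", ".join(_collinear_columns(X))
        )
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=maxiter, tol=1e-10)
    mu = res.predict(X)
    score = X.to_numpy().T @ (y.to_numpy() - mu.to_numpy())
    score_norm = float(np.max(np.abs(score)))
    converged = bool(res.converged) and score_norm < max(score_tol, 1e-6 * len(rows))
    flags = []
    if not converged:
        flags.append("non-convergence")
        logger.warning("logistic fit did not converge (score norm %.3g)", score_norm)
    big = res.params[res.params.abs() > separation_threshold]
    for term in big.index:
        if term != "Intercept":
            flags.append(f"possible separation: {term}")
            logger.warning("possible separation on %s (coef %.2f)", term, big[term])
    table = pd.DataFrame(
        {
            "term": res.params.index,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
        }
    )
    with np.errstate(over="ignore"):
        table["or"] = np.exp(table["coef"])
        table["ci_low"] = np.exp(table["coef"] - Z95 * table["se"])
        table["ci_high"] = np.exp(table["coef"] + Z95 * table["se"])
    return FitResult(
        params=res.params,
        bse=res.bse,
        table=table,
        reference_levels=refs,
        converged=converged,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", maxiter))
        if hasattr(res, "fit_history") else maxiter,
        score_norm=score_norm,
        flags=flags,
    )


def stratified_analysis(
    cohort: pd.DataFrame,
    models: tuple[str, ...] = ("bivariable", "minimal", "full"),
) -> dict[str, dict]:
    """Per-utilization-stratum prevalences, 2x2 ORs, and adjusted models.

    Returns ``{stratum: {"prevalence": DataFrame, "bivariable": {group:
    OREstimate}, "minimal": FitResult, "full": FitResult}}`` with the
    unexposed group as reference throughout.  Empty strata are skipped
    with a warning; model keys appear only when requested and fittable.
    """
    out: dict[str, dict] = {}
    for stratum in ("LOW", "MEDIUM", "HIGH"):
        sub = cohort[cohort["stratum"] == stratum]
        if not len(sub):
            logger.warning("stratum %s is empty; skipped", stratum)
            continue
        res: dict = {}
        counts = (
            sub.groupby("exposure_group", observed=False)["outcome"]
            .agg(cases="sum", total="count")
            .reindex(EXPOSURE_ORDER)
            .fillna(0)
            .astype(int)
        )
        counts["noncases"] = counts["total"] - counts["cases"]
        counts["prevalence_pct"] = [
            round_half_up(prevalence(r.cases, r.noncases), 2) if r.total else float("nan")
            for r in counts.itertuples()
        ]
        res["prevalence"] = counts.reset_index()[
            ["exposure_group", "cases", "noncases", "total", "prevalence_pct"]
        ]
        if "bivariable" in models:
            ref = counts.loc["NEITHER"]
            ors = {}
            for grp in ("TBI_ONLY", "PTSD_ONLY", "COMORBID"):
                row = counts.loc[grp]
                if row.total == 0:
                    continue
                ors[grp] = odds_ratio(
                    ContingencyTable(
                        int(row.cases), int(row.noncases), int(ref.cases), int(ref.noncases)
                    )
                )
            res["bivariable"] = ors
        for adj in ("minimal", "full"):
            if adj in models and 0 < sub["outcome"].sum() < len(sub):
                res[adj] = fit_logistic(sub, ModelSpec(adjustment=adj))
        out[stratum] = res
    return out
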