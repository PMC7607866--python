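"""Clinical statistics on global 5mC/5hmC levels.

Global modification levels (percent of cytosines, mass-spectrometry style)
are compared between normal plasma cells (NPC) and newly diagnosed myeloma
(NDMM), across ISS stages, and against age/sex; survival is analysed by
dichotomising patients at the median analyte level (Kaplan-Meier, log-rank,
and a univariate Cox model). The hazard ratio is oriented low-versus-high,
so HR > 1 means the low-5hmC half fares worse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalResult",
    "percent_reduction",
    "compare_conditions",
    "iss_trend",
    "covariate_association",
    "dichotomized_survival",
    "ANALYTE_COLUMNS",
]

ANALYTE_COLUMNS = {"mc": "mc_percent", "hmc": "hmc_percent"}


@dataclass
class SurvivalResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float                 # log-rank
    n_low: int
    n_high: int
    split_value: float
    zero_event_group: bool   # HR unstable when a group has no events

    def as_dict(self) -> dict:
        return asdict(self)


def percent_reduction(reference, test) -> float:
    """Percent drop of the test mean relative to the reference mean."""
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    m_ref = ref.mean()
    if m_ref <= 0:
        raise ValueError("reference mean must be positive")
    return float(100.0 * (m_ref - tst.mean()) / m_ref)


def _analyte(samples: pd.DataFrame, analyte: str, subset: pd.Series) -> np.ndarray:
    col = ANALYTE_COLUMNS[analyte]
    vals = samples.loc[subset, col]
    n_missing = int(vals.isna().sum())
    if n_missing:
        logger.info("dropping %d samples with missing %s", n_missing, col)
    return vals.dropna().to_numpy(dtype=float)


def compare_conditions(samples: pd.DataFrame, analyte: str) -> tuple[float, float]:
    """NPC versus NDMM-at-diagnosis: (percent reduction, Mann-Whitney p)."""
    ref = _analyte(samples, analyte, samples["condition"] == "NPC")
    tst = _analyte(samples, analyte, samples["condition"] == "NDMM")
    if len(ref) < 2 or len(tst) < 2:
        raise ValueError("need at least 2 samples per condition")
    reduction = percent_reduction(ref, tst)
    p = float(stats.mannwhitneyu(ref, tst, alternative="two-sided").pvalue)
    return reduction, p


def iss_trend(samples: pd.DataFrame, analyte: str) -> pd.DataFrame:
    """Stage means plus I-vs-II and I-vs-III reductions with rank-test p's.

    NA-stage samples are excluded. Returns a frame with one row per
    comparison: stage, n, mean, reduction_vs_I, p_vs_I.
    """
    ndmm = samples[samples["condition"] == "NDMM"]
    stage_vals = {}
    for stage in ("I", "II", "III"):
        vals = _analyte(ndmm, analyte, ndmm["iss"] == stage)
        if len(vals) < 2:
            raise ValueError(f"ISS stage {stage} has fewer than 2 usable samples")
        stage_vals[stage] = vals
    rows = []
    for stage in ("I", "II", "III"):
        vals = stage_vals[stage]
        row = {"stage": stage, "n": len(vals), "mean": float(vals.mean())}
        if stage == "I":
            row["reduction_vs_I"] = 0.0
            row["p_vs_I"] = np.nan
        else:
            row["reduction_vs_I"] = percent_reduction(stage_vals["I"], vals)
            row["p_vs_I"] = float(
                stats.mannwhitneyu(stage_vals["I"], vals, alternative="two-sided").pvalue
            )
        rows.append(row)
    return pd.DataFrame(rows)


def covariate_association(
    samples: pd.DataFrame, analyte: str, covariate: str
) -> tuple[float, float]:
    """Association of the analyte with age (Pearson) or sex (Mann-Whitney).

    Returns (statistic, p): Pearson r and its t-test p for age; the
    Mann-Whitney U and its p for sex.
    """
    col = ANALYTE_COLUMNS[analyte]
    ndmm = samples[samples["condition"] == "NDMM"].dropna(subset=[col, covariate])
    y = ndmm[col].to_numpy(dtype=float)
    if covariate == "age":
        x = ndmm["age"].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError("constant covariate: age")
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if covariate == "sex":
        groups = [y[ndmm["sex"] == s] for s in sorted(ndmm["sex"].unique())]
        if len(groups) != 2 or min(len(g) for g in groups) == 0:
            raise ValueError("constant covariate: sex")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unsupported covariate {covariate!r}")


def dichotomized_survival(
    samples: pd.DataFrame, analyte: str = "hmc", split: str = "median"
) -> tuple[SurvivalResult, dict[str, pd.DataFrame]]:
    """Median-split survival analysis of NDMM patients on a global analyte.

    Samples at or below the median go to the "low" group (the median sample
    itself is low, giving a 20/19 split at n = 39). Kaplan-Meier curves are
    fitted per group, group separation is tested by log-rank, and the
    hazard ratio of low versus high comes from a univariate Cox model with
    a 95% Wald interval.
    """
    if split != "median":
        raise ValueError("only the median split is implemented")
    col = ANALYTE_COLUMNS[analyte]
    ndmm = samples[samples["condition"] == "NDMM"].dropna(subset=[col]).copy()
    if int(ndmm["os_event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    med = float(ndmm[col].median())
    ndmm["low"] = (ndmm[col] <= med).astype(int)
    low, high = ndmm[ndmm["low"] == 1], ndmm[ndmm["low"] == 0]

    km: dict[str, pd.DataFrame] = {}
    for label, grp in (("low", low), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["os_months"], grp["os_event"], label=label)
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        km[label] = curve

    lr = logrank_test(
        low["os_months"], high["os_months"], low["os_event"], high["os_event"]
    )
    zero_events = int(low["os_event"].sum()) == 0 or int(high["os_event"].sum()) == 0
    cph = CoxPHFitter()
    cph.fit(
        ndmm[["os_months", "os_event", "low"]],
        duration_col="os_months",
        event_col="os_event",
    )
    summary = cph.summary.loc["low"]
    result = SurvivalResult(
        hr=float(np.exp(summary["coef"])),
        ci_low=float(np.exp(summary["coef lower 95%"])),
        ci_high=float(np.exp(summary["coef upper 95%"])),
        p=float(lr.p_value),
        n_low=len(low),
        n_high=len(high),
        split_value=med,
        zero_event_group=zero_events,
    )
    return result, km
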