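"""Immunohistochemistry staging statistics.

Per-sample percent-positive nuclei, per-stage mean/SD/SEM summaries, and
two-sample Student t-tests between disease stages computed directly from
summary statistics (mean, SEM, n) — the form in which published staging
tables report their data. The pooled-variance (classic Student) test is
the default; Welch's unequal-variance variant is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("normal_GEJ", "barretts", "dysplastic_barretts", "adenocarcinoma")


@dataclass
class StageSummary:
    stage: str
    n: int
    mean_pct: float
    sd_pct: float
    sem_pct: float
    sem_defined: bool = True

    @classmethod
    def from_mean_sem(cls, stage: str, n: int, mean_pct: float, sem_pct: float) -> "StageSummary":
        """Recover the SD from a published mean/SEM pair: SD = SEM * sqrt(n)."""
        if n < 2:
            raise ValueError("mean/SEM summaries need n >= 2")
        return cls(stage=stage, n=n, mean_pct=mean_pct,
                   sd_pct=sem_pct * math.sqrt(n), sem_pct=sem_pct)


@dataclass
class TTestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    variant: str
    flag: str = ""


def percent_positive(counts: pd.DataFrame) -> pd.Series:
    """100 x stained/total per sample; requires columns sample,
    total_nuclei, stained_nuclei."""
    total = counts["total_nuclei"].to_numpy()
    stained = counts["stained_nuclei"].to_numpy()
    if np.any(total <= 0):
        raise ValueError("total_nuclei must be positive")
    if np.any((stained < 0) | (stained > total)):
        raise ValueError("stained_nuclei must lie in [0, total_nuclei]")
    return pd.Series(100.0 * stained / total, index=counts["sample"].to_numpy(),
                     name="pct_positive")


def summarize_stage(pcts, stage: str) -> StageSummary:
    """Sample-level mean, SD (n-1 denominator) and SEM of percentages."""
    x = np.asarray(pcts, dtype=np.float64)
    if len(x) == 0:
        raise ValueError("need at least one sample")
    if len(x) == 1:
        return StageSummary(stage, 1, float(x[0]), float("nan"), float("nan"),
                            sem_defined=False)
    sd = float(np.std(x, ddof=1))
    return StageSummary(stage, len(x), float(np.mean(x)), sd, sd / math.sqrt(len(x)))


def pooled_t_from_summary(a: StageSummary, b: StageSummary, welch: bool = False) -> TTestResult:
    """Two-sample t-test from per-group mean, SD and n.

    Pooled-variance Student t by default: s2 = ((na-1)sa^2 + (nb-1)sb^2) /
    (na+nb-2), t = (ma-mb)/sqrt(s2(1/na+1/nb)), df = na+nb-2, two-sided p.
    ``welch=True`` uses the unequal-variance statistic with
    Welch-Satterthwaite degrees of freedom.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    dm = a.mean_pct - b.mean_pct
    va, vb = a.sd_pct ** 2, b.sd_pct ** 2
    variant = "welch" if welch else "pooled"
    if welch:
        se2 = va / a.n + vb / b.n
        if se2 == 0:
            return _degenerate(a, b, dm, float(a.n + b.n - 2), variant)
        t = dm / math.sqrt(se2)
        df = se2 ** 2 / ((va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1))
    else:
        df = float(a.n + b.n - 2)
        s2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        if s2 == 0:
            return _degenerate(a, b, dm, df, variant)
        t = dm / math.sqrt(s2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(a.stage, b.stage, float(t), float(df), min(1.0, p), variant)


def _degenerate(a, b, dm, df, variant):
    if dm == 0:
        return TTestResult(a.stage, b.stage, 0.0, df, 1.0, variant,
                           flag="zero variance, equal means")
    return TTestResult(a.stage, b.stage, math.copysign(math.inf, dm), df, 0.0,
                       variant, flag="zero variance, unequal means")


def summaries_from_counts(counts: pd.DataFrame) -> dict[str, StageSummary]:
    """Per-stage summaries from a sample-level nucleus-count table."""
    pcts = percent_positive(counts)
    out = {}
    for stage, sub in counts.groupby("stage", sort=False):
        out[str(stage)] = summarize_stage(pcts[sub["sample"].to_numpy()], str(stage))
    return out


def stage_contrast_report(summaries: dict[str, StageSummary], reference_stage: str,
                          welch: bool = False) -> pd.DataFrame:
    """Reference stage vs every other stage, one t-test per contrast."""
    if reference_stage not in summaries:
        raise ValueError(f"reference stage {reference_stage!r} not present")
    ref = summaries[reference_stage]
    rows = []
    for stage, summ in summaries.items():
        if stage == reference_stage:
            continue
        if summ.n < 2 or ref.n < 2:
            rows.append({"reference": reference_stage, "stage": stage,
                         "t": np.nan, "df": np.nan, "p": np.nan,
                         "variant": "welch" if welch else "pooled",
                         "flag": "n < 2: contrast unavailable"})
            continue
        r = pooled_t_from_summary(ref, summ, welch=welch)
        rows.append({"reference": reference_stage, "stage": stage, "t": r.t,
                     "df": r.df, "p": r.p, "variant": r.variant, "flag": r.flag})
    return pd.DataFrame(rows)


def table1_summaries() -> dict[str, StageSummary]:
    """The published staging table: n, mean % positive nuclei, SEM."""
    published = {
        "normal_GEJ": (5, 61.6, 3.3),
        "barretts": (11, 42.2, 7.6),
        "dysplastic_barretts": (6, 4.8, 2.0),
        "adenocarcinoma": (20, 3.3, 2.0),
    }
    return {stage: StageSummary.from_mean_sem(stage, n, mean, sem)
            for stage, (n, mean, sem) in published.items()}
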