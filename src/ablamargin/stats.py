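"""Group statistics for the 30-patient ablation-margin cohort.

Ships the transcribed per-patient outcome table (14 patients with local
tumor progression, LTP; 16 LTP-free) as a package resource: minimum distance
to agreement (DTA) between the mapped tumor and the ablation zone, and the
percentage / absolute tumor volume mapped outside the ablation zone, each
under rigid-only and rigid+deformable registration.  Values are stored
exactly as published, with no unit conversion.

The comparison between groups uses the Mann–Whitney U test — the data are
unpaired and the minimum DTA is censored at its closed lower limit of 0 mm —
and discrimination is summarized as ROC AUC, computed by the rank-sum
identity AUC = U / (n_a · n_b) with ties counted one half.  Summary rows use
the population standard deviation (ddof = 0), the convention under which the
published pooled values reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = [
    "PatientRecord",
    "GroupSummary",
    "NUMERIC_COLUMNS",
    "load_table2_fixture",
    "table2_frame",
    "mann_whitney_u",
    "roc_auc",
    "summarize",
]

NUMERIC_COLUMNS = (
    "dta_rigid",
    "dta_deformed",
    "pct_rigid",
    "pct_deformed",
    "cc_rigid",
    "cc_deformed",
)


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: group label plus the six outcome columns."""

    patient_id: int
    group: str  # "LTP" | "LTP-free"
    dta_rigid: float
    dta_deformed: float
    pct_rigid: float
    pct_deformed: float
    cc_rigid: float
    cc_deformed: float


@dataclass(frozen=True)
class GroupSummary:
    column: str
    grouping: str
    n: int
    mean: float
    std: float  # population (ddof = 0)
    median: float
    min: float
    max: float


def table2_frame() -> pd.DataFrame:
    """The cohort table as a DataFrame (30 rows, verbatim values)."""
    with resources.files("ablamargin.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2_fixture() -> list[PatientRecord]:
    """The 30 transcribed patient records (14 LTP, then 16 LTP-free)."""
    df = table2_frame()
    return [PatientRecord(**row) for row in df.to_dict("records")]


def mann_whitney_u(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (midranks for ties) and its p-value.

    Returns U for group a.  The p-value is exact by enumeration when
    n_a * n_b <= 400 and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = rankdata(pooled)
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return u_a, float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """AUC = P(score of a random positive > score of a random negative), ties ½.

    ``labels`` are 0/1 (or boolean); computed by the rank-sum identity, so it
    equals U_positive / (n_pos · n_neg) from :func:`mann_whitney_u`.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def summarize(
    records: list[PatientRecord] | pd.DataFrame,
    column: str,
    grouping: str = "pooled",
) -> GroupSummary:
    """Mean, population std, median, min, max of one column for one grouping.

    ``grouping`` is "pooled" or a group label present in the data.
    """
    if column not in NUMERIC_COLUMNS:
        raise KeyError(f"unknown column {column!r}; expected one of {NUMERIC_COLUMNS}")
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if grouping != "pooled":
        df = df[df["group"] == grouping]
    if df.empty:
        raise ValueError(f"no records for grouping {grouping!r}")
    v = df[column].to_numpy(dtype=float)
    return GroupSummary(
        column=column,
        grouping=grouping,
        n=len(v),
        mean=float(v.mean()),
        std=float(v.std(ddof=0)),
        median=float(np.median(v)),
        min=float(v.min()),
        max=float(v.max()),
    )


def cohort_report() -> dict:
    """All headline cohort statistics in one dictionary (2 dp like the source)."""
    df = table2_frame()
    ltp = df[df.group == "LTP"]
    free = df[df.group == "LTP-free"]
    u, p = mann_whitney_u(ltp.dta_deformed, free.dta_deformed)
    labels = (df.group == "LTP-free").to_numpy()
    return {
        "pct_rigid_pooled_mean": round(summarize(df, "pct_rigid").mean, 2),
        "pct_rigid_pooled_std": round(summarize(df, "pct_rigid").std, 2),
        "pct_deformed_pooled_mean": round(summarize(df, "pct_deformed").mean, 2),
        "pct_deformed_pooled_std": round(summarize(df, "pct_deformed").std, 2),
        "pct_rigid_ltp_mean": round(summarize(df, "pct_rigid", "LTP").mean, 2),
        "pct_deformed_ltp_mean": round(summarize(df, "pct_deformed", "LTP").mean, 2),
        "pct_rigid_ltp_free_mean": round(summarize(df, "pct_rigid", "LTP-free").mean, 2),
        "cc_rigid_ltp_mean": round(summarize(df, "cc_rigid", "LTP").mean, 2),
        "cc_deformed_ltp_mean": round(summarize(df, "cc_deformed", "LTP").mean, 2),
        "auc_deformed": round(roc_auc(df.dta_deformed, labels), 2),
        "auc_rigid": round(roc_auc(df.dta_rigid, labels), 2),
        "mwu_u_deformed": u,
        "mwu_p_deformed": p,
        "n_ltp": int(len(ltp)),
        "n_ltp_free": int(len(free)),
    }
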