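"""Two-way ANOVA decomposition, ICC(A,1) with F-based confidence intervals,
SEM, interpretation bands, and study-level reliability reports.

The reliability model is the two-way random-effects, absolute-agreement,
single-measures intraclass correlation — ICC(A,1) in McGraw & Wong's
taxonomy, often written ICC(2,1). For a complete n x k ratings matrix
(n targets = datasets, k raters or sessions) with mean squares MSR (rows),
MSC (columns) and MSE (residual):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

The 95% CI uses the F-statistic method with a Satterthwaite denominator df.
Absolute reliability is the standard error of measurement, SEM = sqrt(MSE),
in the units of the ratings (here ms of PN latency).

Interpretation bands: > 0.8 excellent; 0.6-0.8 good (both boundaries closed
into "good"); 0.4 <= icc < 0.6 moderate; < 0.4 poor. Negative point
estimates are reported as computed (never clamped) and banded "poor".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AnovaDecomposition",
    "ICCResult",
    "two_way_anova",
    "icc_a1",
    "sem_from_anova",
    "interpret_icc",
    "pivot_ratings",
    "reliability_report",
]


@dataclass
class RatingsMatrix:
    """Complete n_targets x k_raters matrix of ratings (no missing cells)."""

    values: np.ndarray
    target_ids: list | None = None
    rater_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must form a 2-D matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 targets and 2 raters, got {n} x {k}")
        if not np.isfinite(self.values).all():
            raise ValueError("ratings matrix contains missing or non-finite cells")
        if self.target_ids is None:
            self.target_ids = list(range(n))
        if self.rater_ids is None:
            self.rater_ids = list(range(k))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaDecomposition:
    """Two-way, one-observation-per-cell sums of squares and mean squares."""

    ss_rows: float
    ss_cols: float
    ss_error: float
    df_rows: int
    df_cols: int
    df_error: int
    msr: float
    msc: float
    mse: float

    @property
    def ss_total(self) -> float:
        return self.ss_rows + self.ss_cols + self.ss_error


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    sem: float
    n: int
    k: int
    alpha: float
    band: str


def two_way_anova(m: RatingsMatrix) -> AnovaDecomposition:
    """Standard two-way decomposition with one observation per cell.

    SS_rows (between targets, df n-1), SS_cols (between raters, df k-1) and
    the residual SS_error (df (n-1)(k-1)); SS_total = SS_rows + SS_cols +
    SS_error exactly.
    """
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid**2).sum())
    df_rows, df_cols, df_error = n - 1, k - 1, (n - 1) * (k - 1)
    return AnovaDecomposition(
        ss_rows=ss_rows,
        ss_cols=ss_cols,
        ss_error=ss_error,
        df_rows=df_rows,
        df_cols=df_cols,
        df_error=df_error,
        msr=ss_rows / df_rows,
        msc=ss_cols / df_cols,
        mse=ss_error / df_error,
    )


def sem_from_anova(a: AnovaDecomposition) -> float:
    """Standard error of measurement: sqrt(MSE), in rating units (ms)."""
    return float(np.sqrt(a.mse))


def interpret_icc(icc: float) -> str:
    """Band an ICC: >0.8 excellent; [0.6, 0.8] good; [0.4, 0.6) moderate;
    <0.4 (including negative estimates) poor."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc > 0.8:
        return "excellent"
    if icc >= 0.6:
        return "good"
    if icc >= 0.4:
        return "moderate"
    return "poor"


def icc_a1(m: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    The two-sided (1 - alpha) CI is the F-based interval with Satterthwaite
    denominator degrees of freedom. Degenerate inputs: a matrix whose cells
    are all identical carries no information and raises; identical columns
    with varying rows give icc = 1, sem = 0 with a point CI.
    """
    a = two_way_anova(m)
    n, k = m.n, m.k
    if a.msr == 0.0 and a.msc == 0.0 and a.mse == 0.0:
        raise ValueError("degenerate ratings: all values identical")

    denom = a.msr + (k - 1) * a.mse + (k / n) * (a.msc - a.mse)
    icc = (a.msr - a.mse) / denom
    sem = sem_from_anova(a)

    if a.mse == 0.0 and a.msc == 0.0:
        # perfect absolute agreement with real target variance
        return ICCResult(1.0, 1.0, 1.0, 0.0, n, k, alpha, interpret_icc(1.0))

    # F-based CI (two-way random, absolute agreement, single measures)
    if 1.0 - icc <= 1e-12:
        ci_low, ci_high = icc, 1.0
    else:
        ca = k * icc / (n * (1.0 - icc))
        cb = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc))
        num = (ca * a.msc + cb * a.mse) ** 2
        den = (ca * a.msc) ** 2 / (k - 1) + (cb * a.mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else 1.0
        v = max(v, 1.0)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        mix = k * a.msc + (k * n - k - n) * a.mse
        ci_low = n * (a.msr - f_l * a.mse) / (f_l * mix + n * a.msr)
        ci_high = n * (f_u * a.msr - a.mse) / (mix + n * f_u * a.msr)
        ci_low = min(ci_low, icc)
        ci_high = max(ci_high, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        sem=sem,
        n=n,
        k=k,
        alpha=alpha,
        band=interpret_icc(float(icc)),
    )


# ---------------------------------------------------------------------------
# Study-level reports
# ---------------------------------------------------------------------------

#: design name -> how the ratings matrix is assembled per condition
DESIGNS = ("intra_session", "inter_session", "inter_rater")
_INTRA_SESSIONS = {"intra_session": (1, 2), "inter_session": (1, 3)}


def pivot_ratings(
    labels: pd.DataFrame,
    condition: str,
    rater_id: str | None = None,
    sessions: Sequence[int] | None = None,
    session: int | None = None,
) -> RatingsMatrix:
    """Build a datasets x (sessions or raters) matrix from a long label table.

    ``labels`` columns: dataset_id, condition, rater_id, session, pn_ms.
    Either fix a rater and take columns = ``sessions`` (intra-rater designs),
    or fix a ``session`` and take columns = all raters (inter-rater design).
    Raises ``ValueError`` naming any missing cell.
    """
    sub = labels[labels["condition"] == condition]
    if rater_id is not None:
        sub = sub[(sub["rater_id"] == rater_id) & (sub["session"].isin(sessions))]
        piv = sub.pivot_table(
            index="dataset_id", columns="session", values="pn_ms", aggfunc="first"
        ).reindex(columns=list(sessions))
        col_desc = [f"{rater_id}/s{s}" for s in sessions]
    elif session is not None:
        sub = sub[sub["session"] == session]
        raters = sorted(sub["rater_id"].unique())
        piv = sub.pivot_table(
            index="dataset_id", columns="rater_id", values="pn_ms", aggfunc="first"
        ).reindex(columns=raters)
        col_desc = [f"{r}/s{session}" for r in raters]
    else:
        raise ValueError("specify either rater_id+sessions or session")
    if piv.isna().any().any():
        missing = [
            f"(condition={condition}, dataset={d}, column={c})"
            for d, c in zip(*np.where(piv.isna().values))
            for d, c in [(piv.index[d], piv.columns[c])]
        ]
        raise ValueError("incomplete label table; missing cells: " + "; ".join(missing))
    return RatingsMatrix(
        values=piv.values, target_ids=list(piv.index), rater_ids=col_desc
    )


def reliability_report(
    labels: pd.DataFrame,
    design: str,
    condition: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Reliability table for one condition under one design.

    * ``intra_session``: one row per rater, sessions 1 vs 2 (n datasets, k=2)
    * ``inter_session``: one row per rater, sessions 1 vs 3 (n datasets, k=2)
    * ``inter_rater``: one row per session, all raters (n datasets, k raters)

    Returns a DataFrame with columns condition, design, unit (rater or
    session), icc, ci_low, ci_high, sem, band, n, k.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    rows = []
    if design in _INTRA_SESSIONS:
        sessions = _INTRA_SESSIONS[design]
        raters = sorted(labels.loc[labels["condition"] == condition, "rater_id"].unique())
        for r in raters:
            m = pivot_ratings(labels, condition, rater_id=r, sessions=sessions)
            res = icc_a1(m, alpha=alpha)
            rows.append((condition, design, r, res))
    else:
        sess = sorted(labels.loc[labels["condition"] == condition, "session"].unique())
        for s in sess:
            m = pivot_ratings(labels, condition, session=int(s))
            res = icc_a1(m, alpha=alpha)
            rows.append((condition, design, f"session{s}", res))
    return pd.DataFrame(
        [
            {
                "condition": c,
                "design": d,
                "unit": u,
                "icc": r.icc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "sem": r.sem,
                "band": r.band,
                "n": r.n,
                "k": r.k,
            }
            for c, d, u, r in rows
        ]
    )
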