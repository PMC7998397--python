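"""Inter-coder agreement: stream alignment, Cohen's kappa and ICC.

Two coders annotating the same session produce two event streams that are
never perfectly time-locked.  ``align_streams`` matches events greedily by
temporal proximity (code-agnostic, within a tolerance), producing a
confusion matrix over code labels with a ``nil`` margin for unmatched
events.  Cohen's kappa summarizes categorical agreement on that matrix.

Per-code count reliability uses the single-measure, two-way, absolute-
agreement intraclass correlation ICC(A,1) of McGraw & Wong, with a
one-sided hypothesis test against a non-zero null value rho0.  The test
statistic is F* = MSR / (a*MSC + b*MSE) with

    a = k*rho0 / (n*(1 - rho0)),    b = 1 + k*rho0*(n - 1) / (n*(1 - rho0)),

df1 = n - 1 and a Satterthwaite (fractional) denominator df.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ethogram import AnnotatedEvent, SessionRecord

__all__ = [
    "AlignmentResult",
    "ReliabilityReport",
    "align_streams",
    "cohens_kappa",
    "per_code_kappa",
    "icc_single",
    "code_count_matrix",
]


def _label(ev: AnnotatedEvent) -> str:
    if ev.code_id == "ENG" and ev.modifier is not None:
        return f"ENG{ev.modifier}"
    return ev.code_id


@dataclass
class AlignmentResult:
    matched: list[tuple[AnnotatedEvent, AnnotatedEvent, float]]
    unmatched_a: list[AnnotatedEvent]
    unmatched_b: list[AnnotatedEvent]
    confusion: pd.DataFrame  # labels of a in rows, b in columns, + "nil"

    @property
    def agreement(self) -> float:
        """Share of matched pairs carrying the same code label."""
        if not self.matched:
            return float("nan")
        same = sum(_label(x) == _label(y) for x, y, _ in self.matched)
        return same / len(self.matched)


def align_streams(
    a: SessionRecord,
    b: SessionRecord,
    tolerance_s: float = 2.0,
) -> AlignmentResult:
    """Greedy nearest-in-time bipartite matching of two coders' streams.

    Candidate pairs within ``tolerance_s`` are taken smallest |dt| first
    (ties broken by time, then input order); each event is matched at most
    once.  State events are located at their start time.  The confusion
    matrix rows index coder *a* labels, columns coder *b*, with a ``nil``
    row/column for unmatched events.
    """
    if a.session_id != b.session_id:
        raise ValueError(
            f"streams code different sessions: {a.session_id!r} vs {b.session_id!r}"
        )
    ev_a, ev_b = list(a.events), list(b.events)
    candidates = [
        (abs(x.time_s - y.time_s), x.time_s, i, j)
        for i, x in enumerate(ev_a)
        for j, y in enumerate(ev_b)
        if abs(x.time_s - y.time_s) <= tolerance_s
    ]
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for dt, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((ev_a[i], ev_b[j], dt))
    unmatched_a = [x for i, x in enumerate(ev_a) if i not in used_a]
    unmatched_b = [y for j, y in enumerate(ev_b) if j not in used_b]

    labels = sorted(
        {_label(e) for e in ev_a} | {_label(e) for e in ev_b} | {"nil"}
    )
    conf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for x, y, _ in matched:
        conf.loc[_label(x), _label(y)] += 1
    for x in unmatched_a:
        conf.loc[_label(x), "nil"] += 1
    for y in unmatched_b:
        conf.loc["nil", _label(y)] += 1
    return AlignmentResult(matched, unmatched_a, unmatched_b, conf)


def cohens_kappa(confusion: "pd.DataFrame | np.ndarray") -> float | None:
    """kappa = (p_o - p_e) / (1 - p_e), expected agreement from marginals.

    Returns ``None`` (with a warning) when the marginals are degenerate
    (p_e = 1, a single category).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) / total) @ (m.sum(axis=0) / total))
    if p_e >= 1.0 - 1e-12:
        warnings.warn("degenerate single-category matrix: kappa undefined")
        return None
    return (p_o - p_e) / (1.0 - p_e)


def per_code_kappa(confusion: pd.DataFrame) -> pd.Series:
    """One-vs-rest kappa per code label from a full confusion matrix."""
    out = {}
    labels = [l for l in confusion.index if l != "nil"]
    m = confusion.to_numpy(dtype=float)
    idx = {l: i for i, l in enumerate(confusion.index)}
    for lab in labels:
        i = idx[lab]
        a = m[i, i]
        b = m[i, :].sum() - a
        c = m[:, i].sum() - a
        d = m.sum() - a - b - c
        out[lab] = cohens_kappa(np.array([[a, b], [c, d]]))
    return pd.Series(out)


def code_count_matrix(
    pairs: list[tuple[SessionRecord, SessionRecord]],
    code_id: str,
) -> np.ndarray:
    """Per-session counts of one code for each of two raters.

    Rows are sessions (the ICC 'subjects'), columns the two coders -- the
    design for per-code count reliability on double-coded videos.
    """
    def _count(s: SessionRecord) -> int:
        return sum(e.code_id == code_id for e in s.events)

    return np.array([[_count(a), _count(b)] for a, b in pairs], dtype=float)


@dataclass
class ReliabilityReport:
    icc: float
    F: float | None
    df1: float
    df2: float | None
    p: float | None
    ci95: tuple[float, float] | None
    rho0: float
    n_subjects: int
    k_raters: int
    degenerate: bool = False


def icc_single(
    ratings: np.ndarray,
    rho0: float = 0.8,
    *,
    alpha: float = 0.05,
) -> ReliabilityReport:
    """ICC(A,1) with a one-sided test of H0: rho <= rho0.

    ``ratings`` is an n_subjects x k_raters matrix with no missing cells.
    Returns the point estimate, the F* statistic with df1 = n-1 and
    fractional Satterthwaite df2, the one-sided p-value and the 95% CI
    (McGraw & Wong).  A matrix with zero total variance is reported as
    ICC = 1 with a degenerate-variance flag.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be 2-D (subjects x raters)")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total <= 1e-300:
        warnings.warn("zero total variance: ICC degenerate, reported as 1")
        return ReliabilityReport(
            icc=1.0, F=None, df1=n - 1, df2=None, p=None, ci95=None,
            rho0=rho0, n_subjects=n, k_raters=k, degenerate=True,
        )

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    def _ab(rho: float) -> tuple[float, float]:
        a = k * rho / (n * (1.0 - rho))
        b = 1.0 + k * rho * (n - 1) / (n * (1.0 - rho))
        return a, b

    def _satterthwaite(a: float, b: float) -> float:
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        return num / den

    a0, b0 = _ab(rho0)
    df1 = n - 1
    denom = a0 * msc + b0 * mse
    if denom <= 0:  # perfect agreement: no rater or error variance at all
        F, df2, p = math.inf, float((n - 1) * (k - 1)), 0.0
    else:
        F = msr / denom
        df2 = _satterthwaite(a0, b0)
        p = float(stats.f.sf(F, df1, df2))

    # 95% CI uses the Satterthwaite df at the *estimated* ICC
    if icc < 1.0:
        a_hat, b_hat = _ab(max(icc, 0.0)) if icc < 1 else (np.inf, np.inf)
        v = _satterthwaite(a_hat, b_hat)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    else:
        ci = (1.0, 1.0)

    return ReliabilityReport(
        icc=float(icc), F=float(F), df1=df1, df2=float(df2), p=p, ci95=ci,
        rho0=rho0, n_subjects=n, k_raters=k,
    )
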