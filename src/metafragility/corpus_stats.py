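"""Corpus-level summaries of fragility measures across meta-analyses.

Given one fragility record per significant meta-analysis (index, quotient,
pooled P value, sample size), this module computes the descriptive
statistics a meta-research survey reports: medians with interquartile
ranges and ranges, cumulative-count distribution curves, and Pearson
correlations (with Fisher-z confidence intervals) between the fragility
measures and the pooled P values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtri
from scipy.stats import t as t_dist


@dataclass(frozen=True)
class CorpusRecord:
    """Fragility result of one included (significant) meta-analysis."""

    meta_id: str
    index: int
    quotient_pct: float
    p_value: float
    sample_size: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson product-moment correlation with Fisher-z CI and t-test P."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class FiveNumber:
    """Median, quartiles and range of one fragility measure."""

    median: float
    q25: float
    q75: float
    min: float
    max: float


@dataclass(frozen=True)
class CorpusSummary:
    """Descriptive statistics of a fragility corpus.

    ``index_cumsum`` / ``quotient_cumsum`` are the empirical cumulative
    counts: for each distinct observed value, the number of meta-analyses
    with a fragility measure at or below it.  Correlations are ``None``
    when undefined (fewer than 3 records or a constant measure).
    """

    n_records: int
    index_stats: FiveNumber
    quotient_stats: FiveNumber
    index_cumsum: tuple[tuple[float, int], ...]
    quotient_cumsum: tuple[tuple[float, int], ...]
    pearson_index_p: CorrelationResult | None
    pearson_quotient_p: CorrelationResult | None


def pearson_with_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> CorrelationResult:
    """Pearson correlation with confidence interval and two-sided P value.

    The coefficient is the product-moment formula; the CI comes from the
    Fisher z-transform ``artanh(r)`` with variance ``1 / (n - 3)``; the P
    value from the statistic ``r * sqrt((n - 2) / (1 - r^2))`` against the
    t distribution with ``n - 2`` degrees of freedom, two-sided.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 observations, or a constant input
        vector (the correlation is undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ValueError(f"x and y must be 1-d of equal length, got {xa.size} and {ya.size}")
    n = int(xa.size)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    xd = xa - xa.mean()
    yd = ya - ya.mean()
    sxx = float(xd @ xd)
    syy = float(yd @ yd)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("undefined correlation: an input vector is constant")
    r = float(xd @ yd) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))

    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(t_dist.sf(abs(tstat), n - 2))

    if n <= 3 or abs(r) == 1.0:
        # Fisher-z variance 1/(n-3) degenerates; fall back to the trivial bounds
        lo, hi = (r, r) if abs(r) == 1.0 else (-1.0, 1.0)
    else:
        zr = math.atanh(r)
        zc = float(ndtri(1.0 - (1.0 - conf) / 2.0))
        half = zc / math.sqrt(n - 3)
        lo, hi = math.tanh(zr - half), math.tanh(zr + half)
    return CorrelationResult(r=r, ci_low=lo, ci_high=hi, p=min(p, 1.0), n=n)


def _five_number(values: np.ndarray) -> FiveNumber:
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return FiveNumber(
        median=float(med), q25=float(q25), q75=float(q75),
        min=float(values.min()), max=float(values.max()),
    )


def _cumulative_counts(values: np.ndarray) -> tuple[tuple[float, int], ...]:
    distinct = np.unique(values)
    counts = np.searchsorted(np.sort(values), distinct, side="right")
    return tuple((float(v), int(c)) for v, c in zip(distinct, counts))


def summarize(
    records: Sequence[CorpusRecord], conf: float = 0.95, log2_scale: bool = False
) -> CorpusSummary:
    """Summarise a corpus of fragility records.

    Quartiles use the linear-interpolation convention between order
    statistics.  With ``log2_scale=True`` the correlations with the pooled
    P values are computed on log2-transformed fragility measures (the scale
    sometimes used for display); the default is the raw scale.
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty corpus")
    idx = np.array([r.index for r in records], dtype=float)
    quo = np.array([r.quotient_pct for r in records], dtype=float)
    pv = np.array([r.p_value for r in records], dtype=float)

    def corr(values: np.ndarray) -> CorrelationResult | None:
        if values.size < 3:
            return None
        v = np.log2(values) if log2_scale else values
        try:
            return pearson_with_ci(v, pv, conf=conf)
        except ValueError:
            return None

    return CorpusSummary(
        n_records=len(records),
        index_stats=_five_number(idx),
        quotient_stats=_five_number(quo),
        index_cumsum=_cumulative_counts(idx),
        quotient_cumsum=_cumulative_counts(quo),
        pearson_index_p=corr(idx),
        pearson_quotient_p=corr(quo),
    )
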