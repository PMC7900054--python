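"""Domain types and pooling engines for meta-analyses of 2x2 tables.

A meta-analysis of a dichotomous outcome combines several randomised
comparisons, each summarised by a 2x2 table (arm x event status), into a
pooled ratio measure (relative risk or odds ratio) with a Wald confidence
interval on the log scale.  Two pooling engines are provided:

* fixed-effect Mantel-Haenszel, with the Greenland-Robins variance for the
  log pooled ratio (robust to sparse cells);
* random-effects DerSimonian-Laird, inverse-variance weighting with the
  moment estimator of the between-trial variance tau^2.

Fisher's exact test (two-sided, minimum-likelihood rule) is also housed
here because the single-trial fragility index recomputes it at every step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
from scipy.special import ndtri

logger = logging.getLogger("metafragility")
logger.addHandler(logging.NullHandler())

#: relative slack used when comparing hypergeometric probabilities to the
#: observed table's probability in the two-sided Fisher rule; absorbs
#: floating-point noise in what is mathematically an exact tie.
FISHER_RELATIVE_TOLERANCE = 1e-7

_FISHER_TOL_NUM = 10**7 + 1  # integer form of (1 + 1e-7)
_FISHER_TOL_DEN = 10**7


class EffectMeasure(str, Enum):
    """Ratio measure pooled across trials."""

    RR = "rr"
    OR = "or"


class PoolingModel(str, Enum):
    """Fixed-effect Mantel-Haenszel or random-effects DerSimonian-Laird."""

    FIXED_MH = "fixed"
    RANDOM_DL = "random"


class ZeroCellPolicy(str, Enum):
    """Continuity-correction rule for trials with empty cells.

    ``CONSTANT_HALF``: add 0.5 to all four cells of any trial with at least
    one zero cell when computing per-trial log effects and variances for
    inverse-variance / DerSimonian-Laird steps.  Mantel-Haenszel sums are
    left uncorrected (they tolerate single zero cells natively).  Trials
    with zero events in both arms carry no information about a ratio
    measure and are excluded from pooling, but still count towards the
    meta-analysis sample size.
    """

    CONSTANT_HALF = "constant-half"


class InvalidTableError(ValueError):
    """Raised when 2x2 counts violate their invariants."""


class InestimableError(ValueError):
    """Raised when no trial carries information about the pooled effect."""


class NotSignificantError(ValueError):
    """Raised when a fragility index is requested for a non-significant result."""


@dataclass(frozen=True)
class TwoByTwoTrial:
    """One randomised comparison: events / non-events per arm.

    Parameters
    ----------
    trial_id
        Label, unique within its meta-analysis.
    events_t, size_t
        Events and number randomised in the intervention arm.
    events_c, size_c
        Events and number randomised in the control arm.
    """

    trial_id: str
    events_t: int
    size_t: int
    events_c: int
    size_c: int

    def __post_init__(self) -> None:
        for name in ("events_t", "size_t", "events_c", "size_c"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise InvalidTableError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.size_t < 1 or self.size_c < 1:
            raise InvalidTableError(
                f"trial {self.trial_id!r}: arm sizes must be >= 1 "
                f"(got {self.size_t}, {self.size_c})"
            )
        if not (0 <= self.events_t <= self.size_t):
            raise InvalidTableError(
                f"trial {self.trial_id!r}: events_t={self.events_t} "
                f"outside [0, {self.size_t}]"
            )
        if not (0 <= self.events_c <= self.size_c):
            raise InvalidTableError(
                f"trial {self.trial_id!r}: events_c={self.events_c} "
                f"outside [0, {self.size_c}]"
            )

    @property
    def sample_size(self) -> int:
        """Total number randomised across both arms."""
        return self.size_t + self.size_c

    @property
    def nonevents_t(self) -> int:
        return self.size_t - self.events_t

    @property
    def nonevents_c(self) -> int:
        return self.size_c - self.events_c


@dataclass(frozen=True)
class PoolingConfig:
    """How a meta-analysis is pooled and judged significant."""

    measure: EffectMeasure = EffectMeasure.RR
    model: PoolingModel = PoolingModel.RANDOM_DL
    alpha: float = 0.05
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.CONSTANT_HALF

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure", EffectMeasure(self.measure))
        object.__setattr__(self, "model", PoolingModel(self.model))
        object.__setattr__(self, "zero_cell_policy", ZeroCellPolicy(self.zero_cell_policy))
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class MetaAnalysisSpec:
    """An ordered set of trials plus its pooling configuration."""

    meta_id: str
    trials: tuple[TwoByTwoTrial, ...]
    config: PoolingConfig = field(default_factory=PoolingConfig)

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        if len(self.trials) < 1:
            raise ValueError(f"meta-analysis {self.meta_id!r} has no trials")
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValueError(
                f"meta-analysis {self.meta_id!r} has duplicate trial ids: {ids}"
            )

    @property
    def sample_size(self) -> int:
        """Total participants over all trials (both arms), including trials
        excluded from pooling by the zero-cell policy."""
        return sum(t.sample_size for t in self.trials)

    @property
    def k(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class PooledResult:
    """Pooled effect on the natural-log scale with its Wald machinery."""

    log_effect: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    q_stat: float
    k: int

    @property
    def effect(self) -> float:
        """Pooled ratio on the natural (exponentiated) scale."""
        return math.exp(self.log_effect)


# ---------------------------------------------------------------------------
# Fisher's exact test, two-sided minimum-likelihood rule
# ---------------------------------------------------------------------------


def _fisher_p_counts(a: int, n1: int, c: int, n2: int) -> float:
    """Two-sided Fisher exact P from raw counts (events a/n1 vs c/n2).

    Sums the probabilities of all tables sharing the observed margins whose
    hypergeometric probability does not exceed that of the observed table
    (up to ``FISHER_RELATIVE_TOLERANCE``).  Probabilities are computed with
    exact integer binomial coefficients, so the tolerance comparison is an
    exact rational comparison and the returned float is correctly rounded.
    """
    m = a + c
    n = n1 + n2
    if m == 0:
        logger.info("Fisher test on an all-zero table: P = 1 by convention")
        return 1.0
    if m == n:
        # every participant had an event: only one table has these margins
        return 1.0
    lo = max(0, m - n2)
    hi = min(m, n1)
    pmf_num = [comb(m, x) * comb(n - m, n1 - x) for x in range(lo, hi + 1)]
    p_obs = pmf_num[a - lo]
    threshold = p_obs * _FISHER_TOL_NUM
    total = sum(v for v in pmf_num if v * _FISHER_TOL_DEN <= threshold)
    p = total / comb(n, n1)
    return min(p, 1.0)


def fisher_exact_two_sided(trial: TwoByTwoTrial) -> float:
    """Two-sided Fisher exact P value for one trial.

    Uses the minimum-likelihood rule: the P value is the sum of the
    probabilities of all 2x2 tables with the observed margins that are at
    most as probable as the observed table.  This matches the convention of
    mainstream implementations (e.g. R's ``fisher.test``); mid-P and
    doubling variants are deliberately not offered.
    """
    return _fisher_p_counts(trial.events_t, trial.size_t, trial.events_c, trial.size_c)


# ---------------------------------------------------------------------------
# Pooling engines
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def z_quantile(alpha: float) -> float:
    """Two-sided standard-normal critical value z_{1-alpha/2}."""
    return float(ndtri(1.0 - alpha / 2.0))


def _wald_p(log_effect: float, se: float) -> float:
    z = abs(log_effect) / se
    return math.erfc(z / math.sqrt(2.0))


def _pool_counts(
    counts: Sequence[tuple[float, float, float, float]],
    measure: EffectMeasure,
    model: PoolingModel,
    alpha: float,
) -> PooledResult:
    """Pool (events_t, size_t, events_c, size_c) tuples.

    Scalar hot path: the fragility search re-pools thousands of slightly
    perturbed count sets per meta-analysis, so this avoids array overhead.
    """
    ys: list[float] = []
    vs: list[float] = []
    rr = measure is EffectMeasure.RR
    R = S = P_gr = 0.0
    for a, n1, c, n2 in counts:
        if a == 0.0 and c == 0.0:
            continue  # no information about a ratio measure
        b = n1 - a
        d = n2 - c
        # inverse-variance ingredients; any zero cell -> +0.5 on all four
        if a == 0.0 or b == 0.0 or c == 0.0 or d == 0.0:
            ac, bc, cc, dc = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            ac, bc, cc, dc = a, b, c, d
        if rr:
            n1c, n2c = ac + bc, cc + dc
            ys.append(math.log((ac * n2c) / (cc * n1c)))
            vs.append(1.0 / ac - 1.0 / n1c + 1.0 / cc - 1.0 / n2c)
        else:
            ys.append(math.log((ac * dc) / (bc * cc)))
            vs.append(1.0 / ac + 1.0 / bc + 1.0 / cc + 1.0 / dc)
        N = n1 + n2
        if model is PoolingModel.FIXED_MH:
            if rr:
                R += a * n2 / N
                S += c * n1 / N
                P_gr += (n1 * n2 * (a + c) - a * c * N) / (N * N)

    k = len(ys)
    if k == 0:
        raise InestimableError("all trials have zero events in both arms")

    sw = swy = sww = 0.0
    for y, v in zip(ys, vs):
        w = 1.0 / v
        sw += w
        swy += w * y
        sww += w * w
    ybar = swy / sw
    q = 0.0
    for y, v in zip(ys, vs):
        q += (y - ybar) ** 2 / v

    if model is PoolingModel.FIXED_MH:
        tau2 = 0.0
        if rr:
            if R <= 0.0 or S <= 0.0:
                raise InestimableError(
                    "Mantel-Haenszel relative risk inestimable: an arm has "
                    "zero events in every trial"
                )
            log_effect = math.log(R / S)
            var = P_gr / (R * S)
        else:
            R = S = s_pr = s_ps_qr = s_qs = 0.0
            for a, n1, c, n2 in counts:
                if a == 0.0 and c == 0.0:
                    continue
                b = n1 - a
                d = n2 - c
                N = n1 + n2
                Ri = a * d / N
                Si = b * c / N
                Pi = (a + d) / N
                Qi = (b + c) / N
                R += Ri
                S += Si
                s_pr += Pi * Ri
                s_ps_qr += Pi * Si + Qi * Ri
                s_qs += Qi * Si
            if R <= 0.0 or S <= 0.0:
                raise InestimableError(
                    "Mantel-Haenszel odds ratio inestimable: a diagonal is "
                    "empty in every trial"
                )
            log_effect = math.log(R / S)
            var = (
                s_pr / (2.0 * R * R)
                + s_ps_qr / (2.0 * R * S)
                + s_qs / (2.0 * S * S)
            )
        se = math.sqrt(var)
    else:
        tau2 = max(0.0, (q - (k - 1)) / (sw - sww / sw)) if k > 1 else 0.0
        swr = swry = 0.0
        for y, v in zip(ys, vs):
            wr = 1.0 / (v + tau2)
            swr += wr
            swry += wr * y
        log_effect = swry / swr
        se = math.sqrt(1.0 / swr)

    z = z_quantile(alpha)
    return PooledResult(
        log_effect=log_effect,
        se=se,
        ci_low=math.exp(log_effect - z * se),
        ci_high=math.exp(log_effect + z * se),
        p_value=_wald_p(log_effect, se),
        tau2=tau2,
        q_stat=q,
        k=k,
    )


def pool(meta: MetaAnalysisSpec) -> PooledResult:
    """Pool a meta-analysis under its configuration.

    Fixed model: Mantel-Haenszel pooled ratio with the Greenland-Robins
    variance for the log effect.  Random model: inverse-variance weights
    ``1 / (v_i + tau^2)`` with the DerSimonian-Laird moment estimator

        tau^2 = max(0, (Q - (k - 1)) / (sum w - sum w^2 / sum w))

    computed on the fixed inverse-variance weights ``w_i = 1 / v_i``.  The
    confidence interval is ``exp(log_effect +/- z * se)`` and the P value
    the two-sided normal tail of ``log_effect / se``.

    Raises
    ------
    InestimableError
        If, after the zero-cell policy, no trial carries information about
        the ratio (e.g. every trial has zero events in both arms).
    """
    cfg = meta.config
    counts = [
        (float(t.events_t), float(t.size_t), float(t.events_c), float(t.size_c))
        for t in meta.trials
    ]
    return _pool_counts(counts, cfg.measure, cfg.model, cfg.alpha)


def is_significant(result: PooledResult, config: PoolingConfig) -> bool:
    """True iff the pooled CI excludes the null ratio of one.

    An interval touching 1.0 exactly counts as including the null (the
    conservative reading of "P at least equal to alpha").  With Wald
    intervals this is equivalent to ``p_value < alpha`` up to floating-point
    rounding of the exponential.
    """
    return result.ci_low > 1.0 or result.ci_high < 1.0
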