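"""Synthetic meta-analysis corpora for exercising the fragility pipeline.

No public corpus of 2x2 trial tables accompanies the kind of meta-research
survey this package supports, so the generator emulates one: a set of
meta-analyses of binomial trials with lognormal arm sizes, Beta-distributed
control event rates, a protective average effect and additive between-trial
heterogeneity on the log relative risk, filtered to those whose pooled
confidence interval excludes the null (the survey inclusion rule).

Defaults target a corpus of 79 included meta-analyses whose fragility-index
distribution is of the same order of magnitude as published surveys of
surgical meta-analyses (median in the low single digits to low teens).

Seeding: one master seed; candidate meta-analysis ``i`` (counting rejected
candidates) draws from ``numpy`` ``SeedSequence(master, spawn_key=(i,))``,
so extending ``n_meta`` never reshuffles earlier meta-analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .meta_model import (
    EffectMeasure,
    InestimableError,
    MetaAnalysisSpec,
    PoolingConfig,
    PoolingModel,
    TwoByTwoTrial,
    is_significant,
    pool,
)


class DegenerateModelError(RuntimeError):
    """Raised when the inclusion filter accepts almost nothing."""


@dataclass(frozen=True)
class CorpusModel:
    """Generative model for a significance-filtered corpus.

    Parameters
    ----------
    n_meta
        Number of included (significant) meta-analyses to collect.
    trials_per_meta
        Inclusive range of the per-meta-analysis trial count (uniform).
    arm_size_median, arm_size_sigma, arm_size_bounds
        Lognormal model for each arm's size: ``exp(Normal(log(median),
        sigma))``, rounded and clipped to the bounds.
    control_rate_mean, control_rate_concentration, control_rate_bounds
        Beta model for the per-meta-analysis control event rate with
        ``a = mean * concentration``, ``b = (1 - mean) * concentration``,
        clipped to the bounds.
    true_log_rr_mean, true_log_rr_sd
        Normal model for the per-meta-analysis true log relative risk.
    tau
        Between-trial SD of the log relative risk within a meta-analysis
        (additive Normal noise, the standard random-effects generative
        model).
    alpha, measure, model
        Pooling configuration used both for the inclusion filter and
        downstream analysis.
    seed
        Master seed; fully determines the corpus.
    """

    n_meta: int = 79
    trials_per_meta: tuple[int, int] = (2, 10)
    arm_size_median: float = 60.0
    arm_size_sigma: float = 0.6
    arm_size_bounds: tuple[int, int] = (10, 2000)
    control_rate_mean: float = 0.15
    control_rate_concentration: float = 10.0
    control_rate_bounds: tuple[float, float] = (0.01, 0.6)
    true_log_rr_mean: float = math.log(0.6)
    true_log_rr_sd: float = 0.3
    tau: float = 0.2
    alpha: float = 0.05
    measure: EffectMeasure = EffectMeasure.RR
    model: PoolingModel = PoolingModel.RANDOM_DL
    seed: int = 0

    def pooling_config(self) -> PoolingConfig:
        return PoolingConfig(measure=self.measure, model=self.model, alpha=self.alpha)


@dataclass(frozen=True)
class SimulatedCorpus:
    """A significance-filtered corpus plus its rejection bookkeeping."""

    specs: tuple[MetaAnalysisSpec, ...]
    n_candidates: int
    n_rejected: int
    model: CorpusModel


def simulate_trial(
    size_t: int,
    size_c: int,
    p_c: float,
    log_rr: float,
    rng: np.random.Generator,
) -> TwoByTwoTrial:
    """Draw one binomial 2x2 trial.

    Control events are Binomial(size_c, p_c); intervention events are
    Binomial(size_t, p_c * exp(log_rr)).
    """
    p_t = p_c * math.exp(log_rr)
    if p_t > 1.0:
        raise ValueError(
            f"implied intervention risk {p_t:.4g} exceeds 1 "
            f"(p_c={p_c}, log_rr={log_rr})"
        )
    return TwoByTwoTrial(
        trial_id="t",
        events_t=int(rng.binomial(size_t, p_t)),
        size_t=int(size_t),
        events_c=int(rng.binomial(size_c, p_c)),
        size_c=int(size_c),
    )


def _candidate_meta(model: CorpusModel, candidate_index: int) -> MetaAnalysisSpec:
    """Draw one candidate meta-analysis from its own child seed stream."""
    ss = np.random.SeedSequence(model.seed, spawn_key=(candidate_index,))
    rng = np.random.default_rng(ss)
    k = int(rng.integers(model.trials_per_meta[0], model.trials_per_meta[1] + 1))
    p_c = float(
        np.clip(
            rng.beta(
                model.control_rate_mean * model.control_rate_concentration,
                (1.0 - model.control_rate_mean) * model.control_rate_concentration,
            ),
            *model.control_rate_bounds,
        )
    )
    meta_log_rr = float(rng.normal(model.true_log_rr_mean, model.true_log_rr_sd))
    lo, hi = model.arm_size_bounds
    mu = math.log(model.arm_size_median)
    trials = []
    for j in range(k):
        size_t = int(np.clip(round(rng.lognormal(mu, model.arm_size_sigma)), lo, hi))
        size_c = int(np.clip(round(rng.lognormal(mu, model.arm_size_sigma)), lo, hi))
        log_rr_j = meta_log_rr + float(rng.normal(0.0, model.tau))
        # keep the implied intervention risk a valid probability
        log_rr_j = min(log_rr_j, math.log(0.99 / p_c))
        trial = simulate_trial(size_t, size_c, p_c, log_rr_j, rng)
        trials.append(
            TwoByTwoTrial(
                trial_id=f"trial_{j + 1}",
                events_t=trial.events_t,
                size_t=trial.size_t,
                events_c=trial.events_c,
                size_c=trial.size_c,
            )
        )
    return MetaAnalysisSpec(
        meta_id=f"meta_{candidate_index + 1}",
        trials=tuple(trials),
        config=model.pooling_config(),
    )


def iter_candidates(model: CorpusModel) -> Iterator[MetaAnalysisSpec]:
    """Endless stream of candidate meta-analyses (before the filter)."""
    i = 0
    while True:
        yield _candidate_meta(model, i)
        i += 1


def simulate_corpus(model: CorpusModel) -> SimulatedCorpus:
    """Draw candidates and retain significant ones until ``n_meta`` collected.

    A candidate is retained when its pooled confidence interval excludes
    one under the model's pooling configuration; rejected candidates are
    counted.  Aborts if the acceptance rate falls below 1/1000, which
    indicates degenerate generator parameters.
    """
    accepted: list[MetaAnalysisSpec] = []
    n_candidates = 0
    for spec in iter_candidates(model):
        n_candidates += 1
        try:
            result = pool(spec)
        except InestimableError:
            result = None
        if result is not None and is_significant(result, spec.config):
            accepted.append(spec)
            if len(accepted) == model.n_meta:
                break
        if n_candidates >= 2000 and len(accepted) < n_candidates / 1000:
            raise DegenerateModelError(
                f"inclusion filter accepted {len(accepted)} of {n_candidates} "
                "candidates (< 1/1000); generator parameters look degenerate"
            )
    return SimulatedCorpus(
        specs=tuple(accepted),
        n_candidates=n_candidates,
        n_rejected=n_candidates - len(accepted),
        model=model,
    )


def construct_two_study_contrast() -> tuple[TwoByTwoTrial, TwoByTwoTrial]:
    """Two constructed trials with near-equal Fisher P but opposite fragility.

    A small trial with a relative risk reduction of about 89% and a much
    larger trial with a reduction of about 20%, both with two-sided Fisher
    exact P near 0.02: the small, high-effect trial has a far lower
    fragility index than the large, low-effect one, illustrating how the
    index penalises small studies.

    The tables were found once by a deterministic grid search over equal-arm
    trials (arm size by 100 from 400 to 1600, control events by 10, with the
    intervention events spanning reductions of 17-23%), keeping tables with
    Fisher P in [0.015, 0.03] and the reduction closest to the nominal
    values; the result is frozen here.
    """
    small = TwoByTwoTrial("small", events_t=1, size_t=100, events_c=9, size_c=100)
    large = TwoByTwoTrial("large", events_t=184, size_t=1300, events_c=230, size_c=1300)
    return small, large
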