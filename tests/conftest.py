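import numpy as np
import pytest

import metafragility as mf


@pytest.fixture(scope="session")
def three_trial_spec() -> mf.MetaAnalysisSpec:
    """Three moderately sized trials with a protective pooled relative risk."""
    trials = (
        mf.TwoByTwoTrial("t1", 12, 120, 24, 118),
        mf.TwoByTwoTrial("t2", 5, 60, 9, 61),
        mf.TwoByTwoTrial("t3", 30, 300, 41, 295),
    )
    return mf.MetaAnalysisSpec("fx3", trials, mf.PoolingConfig(model="fixed"))


@pytest.fixture(scope="session")
def two_trial_spec() -> mf.MetaAnalysisSpec:
    """Two small trials whose pooled fixed-effect relative risk is significant."""
    trials = (
        mf.TwoByTwoTrial("t1", 2, 50, 10, 50),
        mf.TwoByTwoTrial("t2", 3, 60, 12, 60),
    )
    return mf.MetaAnalysisSpec("fx2", trials, mf.PoolingConfig(model="fixed"))


def random_trial(rng: np.random.Generator, max_arm: int = 60) -> mf.TwoByTwoTrial:
    """A random binomial 2x2 trial with a protective effect on average."""
    n1 = int(rng.integers(10, max_arm + 1))
    n2 = int(rng.integers(10, max_arm + 1))
    pc = rng.uniform(0.1, 0.5)
    rrr = rng.uniform(0.2, 0.9)
    a = int(rng.binomial(n1, min(1.0, pc * (1.0 - rrr))))
    c = int(rng.binomial(n2, pc))
    return mf.TwoByTwoTrial("t", a, n1, c, n2)


def random_meta(
    rng: np.random.Generator,
    k_max: int = 3,
    max_arm: int = 60,
    model: str = "random",
) -> mf.MetaAnalysisSpec:
    """A random meta-analysis of 1..k_max binomial trials."""
    k = int(rng.integers(1, k_max + 1))
    trials = []
    for i in range(k):
        t = random_trial(rng, max_arm=max_arm)
        trials.append(
            mf.TwoByTwoTrial(f"t{i}", t.events_t, t.size_t, t.events_c, t.size_c)
        )
    return mf.MetaAnalysisSpec("m", tuple(trials), mf.PoolingConfig(model=model))


@pytest.fixture(scope="session")
def default_corpus() -> tuple[mf.SimulatedCorpus, list[mf.FragilityResult]]:
    """The seeded default synthetic corpus with its fragility results."""
    corpus = mf.simulate_corpus(mf.CorpusModel(seed=20210116))
    frags = [mf.meta_fragility(spec) for spec in corpus.specs]
    return corpus, frags
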