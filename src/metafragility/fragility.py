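"""Fragility statistics for single trials and pooled meta-analyses.

The fragility index of a statistically significant result is the minimum
number of single-participant event-status changes needed to make it
non-significant.  For a single trial (Walsh's construction) events are
added to the arm with the smaller number of events until the two-sided
Fisher exact P value reaches the significance level.  For a meta-analysis
the index generalises to the minimal number of event-status modifications,
spread over one or more included trials, after which the pooled confidence
interval includes the null ratio of one.

The meta-analysis search is exact on small instances and a certified upper
bound on large ones.  Two cheap heuristics establish an upper bound — a
steepest-ascent greedy walk (apply the single modification that maximises
the recomputed pooled P value) and single-rail line searches (spend the
whole budget in one arm of one trial) — and a branch-and-bound pass over
all null-ward modification states below that bound then either certifies
the minimum or improves it.  Steepest ascent alone is not minimal: adding
an event to a near-empty arm can lower the pooled P value (the variance
shrinks faster than the effect moves toward the null) even though that arm
is the cheapest route to non-significance, so a myopic P-maximiser walks
around such valleys and overshoots.  The branch-and-bound pass is skipped
only when the state space below the bound exceeds ``exact_nodes``, in
which case ``FragilityResult.exact`` is False and the index is an upper
bound on the true minimum.

The fragility quotient expresses the index as a percentage of the total
number of participants in the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import comb
from typing import Literal, Sequence, Union

from .meta_model import (
    InestimableError,
    MetaAnalysisSpec,
    NotSignificantError,
    PooledResult,
    TwoByTwoTrial,
    _fisher_p_counts,
    _pool_counts,
    fisher_exact_two_sided,
    logger,
)

#: which single-event moves the meta-analysis search may use.
#: "both": event additions in the null-ward arm and event removals in the
#: opposing arm; "add-only": additions only (the stricter reading of the
#: single-trial construction).
MoveSet = Literal["both", "add-only"]

#: default search-depth cap for the standalone exhaustive oracle.
DEFAULT_DEPTH_CAP = 8

#: default ceiling on the number of count-states the exact refinement of
#: :func:`meta_fragility` may visit before falling back to the heuristic
#: upper bound.
DEFAULT_EXACT_NODES = 50_000


class FragilitySearchError(RuntimeError):
    """Raised when the exhaustive oracle finds no solution within its cap."""


@dataclass(frozen=True)
class Modification:
    """One single-participant event-status change in one arm of one trial.

    ``delta = +1`` converts a non-event to an event; ``delta = -1`` the
    reverse.  Arm sizes never change.
    """

    trial_id: str
    arm: Literal["intervention", "control"]
    delta: int

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "control"):
            raise ValueError(f"arm must be 'intervention' or 'control', got {self.arm!r}")
        if self.delta not in (1, -1):
            raise ValueError(f"delta must be +1 or -1, got {self.delta}")


@dataclass(frozen=True)
class FragilityResult:
    """A fragility index with its provenance.

    ``index`` equals ``len(trace)``; ``terminal`` is the pooled state (or
    the terminal Fisher P value for a single trial) after applying the
    trace; ``converged`` is False when the search saturated before the
    result turned non-significant; ``exact`` is False when the index is an
    upper bound whose minimality could not be certified within the node
    budget.
    """

    index: int
    quotient_pct: float
    trace: tuple[Modification, ...]
    terminal: Union[PooledResult, float]
    converged: bool
    exact: bool = True


def fragility_quotient(index: int, sample_size: int) -> float:
    """Fragility index as a percentage of the analysis sample size."""
    if sample_size < 1:
        raise ValueError(f"sample_size must be >= 1, got {sample_size}")
    if index < 0:
        raise ValueError(f"index must be >= 0, got {index}")
    return 100.0 * index / sample_size


def apply_modification(trial: TwoByTwoTrial, mod: Modification) -> TwoByTwoTrial:
    """Return the trial with one event-status change applied."""
    if mod.trial_id != trial.trial_id:
        raise ValueError(f"modification targets {mod.trial_id!r}, not {trial.trial_id!r}")
    if mod.arm == "intervention":
        return replace(trial, events_t=trial.events_t + mod.delta)
    return replace(trial, events_c=trial.events_c + mod.delta)


def apply_trace(
    meta: MetaAnalysisSpec, trace: Sequence[Modification]
) -> MetaAnalysisSpec:
    """Replay a modification trace on a meta-analysis."""
    trials = {t.trial_id: t for t in meta.trials}
    for mod in trace:
        trials[mod.trial_id] = apply_modification(trials[mod.trial_id], mod)
    return replace(meta, trials=tuple(trials[t.trial_id] for t in meta.trials))


# ---------------------------------------------------------------------------
# Single-trial (Walsh) fragility index
# ---------------------------------------------------------------------------


def walsh_fragility(trial: TwoByTwoTrial, alpha: float = 0.05) -> FragilityResult:
    """Single-trial fragility index.

    Repeatedly converts one non-event to an event in the arm currently
    holding the smaller number of events (ties go to the intervention arm)
    and recomputes the two-sided Fisher exact P value, stopping the first
    time P >= alpha.  The index is the number of conversions.

    Raises
    ------
    NotSignificantError
        If the trial's Fisher P is already >= alpha: the index is defined
        only for significant results.
    """
    p = fisher_exact_two_sided(trial)
    if p >= alpha:
        raise NotSignificantError(
            f"trial {trial.trial_id!r} is not fragile-indexable: "
            f"Fisher P = {p:.4g} >= alpha = {alpha}"
        )
    a, n1 = trial.events_t, trial.size_t
    c, n2 = trial.events_c, trial.size_c
    trace: list[Modification] = []
    converged = True
    while p < alpha:
        if a <= c:
            if a >= n1:
                logger.warning(
                    "trial %r: intervention arm saturated at %d/%d before "
                    "crossing alpha; fragility search did not converge",
                    trial.trial_id, a, n1,
                )
                converged = False
                break
            a += 1
            trace.append(Modification(trial.trial_id, "intervention", +1))
        else:
            if c >= n2:
                logger.warning(
                    "trial %r: control arm saturated at %d/%d before "
                    "crossing alpha; fragility search did not converge",
                    trial.trial_id, c, n2,
                )
                converged = False
                break
            c += 1
            trace.append(Modification(trial.trial_id, "control", +1))
        p = _fisher_p_counts(a, n1, c, n2)
    return FragilityResult(
        index=len(trace),
        quotient_pct=fragility_quotient(len(trace), trial.sample_size),
        trace=tuple(trace),
        terminal=p,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Meta-analysis fragility index
# ---------------------------------------------------------------------------

State = tuple[tuple[int, int], ...]  # ((events_t, events_c), ...) per trial


class _MetaSearch:
    """Shared machinery for the meta-analysis fragility searches."""

    def __init__(self, meta: MetaAnalysisSpec, moves: MoveSet) -> None:
        if moves not in ("both", "add-only"):
            raise ValueError(f"moves must be 'both' or 'add-only', got {moves!r}")
        self.meta = meta
        self.moves = moves
        cfg = meta.config
        self.measure = cfg.measure
        self.model = cfg.model
        self.alpha = cfg.alpha
        self.n1 = tuple(t.size_t for t in meta.trials)
        self.n2 = tuple(t.size_c for t in meta.trials)
        self.ids = tuple(t.trial_id for t in meta.trials)
        self.start: State = tuple((t.events_t, t.events_c) for t in meta.trials)
        self._cache: dict[State, PooledResult | None] = {}

    def pool_state(self, state: State) -> PooledResult | None:
        """Pooled result of a count-state; None when inestimable."""
        res = self._cache.get(state, False)
        if res is not False:
            return res
        counts = [
            (float(s[0]), float(self.n1[i]), float(s[1]), float(self.n2[i]))
            for i, s in enumerate(state)
        ]
        try:
            res = _pool_counts(counts, self.measure, self.model, self.alpha)
        except InestimableError:
            res = None
        self._cache[state] = res
        return res

    def significant(self, state: State) -> bool:
        res = self.pool_state(state)
        return res is not None and (res.ci_low > 1.0 or res.ci_high < 1.0)

    def children(self, state: State) -> list[tuple[State, Modification]]:
        """Null-ward successor states, in tie-break order.

        Order is trial input order, intervention arm before control arm
        within a trial, so ties in the greedy objective resolve
        reproducibly.  The null-ward direction follows the sign of the
        current state's pooled effect.
        """
        res = self.pool_state(state)
        if res is None:
            return []
        below = res.log_effect < 0.0
        out: list[tuple[State, Modification]] = []
        for i, (a, c) in enumerate(state):
            if below:
                # pooled effect < 1: push it up by adding intervention
                # events or removing control events
                if a < self.n1[i]:
                    out.append(
                        (
                            state[:i] + ((a + 1, c),) + state[i + 1:],
                            Modification(self.ids[i], "intervention", +1),
                        )
                    )
                if self.moves == "both" and c > 0:
                    out.append(
                        (
                            state[:i] + ((a, c - 1),) + state[i + 1:],
                            Modification(self.ids[i], "control", -1),
                        )
                    )
            else:
                if c < self.n2[i]:
                    out.append(
                        (
                            state[:i] + ((a, c + 1),) + state[i + 1:],
                            Modification(self.ids[i], "control", +1),
                        )
                    )
                if self.moves == "both" and a > 0:
                    out.append(
                        (
                            state[:i] + ((a - 1, c),) + state[i + 1:],
                            Modification(self.ids[i], "intervention", -1),
                        )
                    )
        return out

    # -- heuristic upper bounds -------------------------------------------

    def greedy(self, max_steps: int) -> tuple[list[Modification], State] | None:
        """Steepest ascent on the pooled P value; None if it saturates."""
        state = self.start
        trace: list[Modification] = []
        for _ in range(max_steps):
            if not self.significant(state):
                return trace, state
            best = None
            best_p = -1.0
            for child, mod in self.children(state):
                res = self.pool_state(child)
                if res is not None and res.p_value > best_p:
                    best, best_p = (child, mod), res.p_value
            if best is None:
                return None
            state = best[0]
            trace.append(best[1])
        return None

    def rail_searches(self, cap: int) -> tuple[list[Modification], State] | None:
        """Best single-rail solution: all moves in one arm of one trial."""
        best: tuple[list[Modification], State] | None = None
        for i in range(len(self.start)):
            for arm in ("intervention", "control"):
                state = self.start
                trace: list[Modification] = []
                limit = cap if best is None else len(best[0]) - 1
                while len(trace) < limit:
                    res = self.pool_state(state)
                    if res is None:
                        break
                    below = res.log_effect < 0.0
                    if arm == "intervention":
                        delta = +1 if below else -1
                    else:
                        delta = -1 if below else +1
                    if self.moves == "add-only" and delta == -1:
                        break
                    a, c = state[i]
                    if arm == "intervention":
                        a += delta
                        if not (0 <= a <= self.n1[i]):
                            break
                    else:
                        c += delta
                        if not (0 <= c <= self.n2[i]):
                            break
                    state = state[:i] + ((a, c),) + state[i + 1:]
                    trace.append(Modification(self.ids[i], arm, delta))
                    if not self.significant(state):
                        if self.pool_state(state) is not None:
                            best = (list(trace), state)
                        break
        return best

    # -- exact refinement --------------------------------------------------

    def branch_and_bound(
        self, bound: int, node_budget: int
    ) -> tuple[tuple[list[Modification], State] | None, bool]:
        """Search all null-ward states at depth < ``bound`` for a shorter
        solution.

        Returns (best solution found or None, completed) where
        ``completed`` is True when the whole space was covered, certifying
        that no solution shorter than the final bound exists.
        """
        best: tuple[list[Modification], State] | None = None
        best_depth = bound
        seen: dict[State, int] = {self.start: 0}
        nodes = 0
        completed = True
        stack: list[tuple[State, int, list[Modification]]] = [(self.start, 0, [])]
        while stack:
            state, depth, trace = stack.pop()
            if depth + 1 >= best_depth:
                continue
            nodes += 1
            if nodes > node_budget:
                completed = False
                break
            for child, mod in self.children(state):
                prev = seen.get(child)
                if prev is not None and prev <= depth + 1:
                    continue
                seen[child] = depth + 1
                res = self.pool_state(child)
                if res is None:
                    continue
                if not (res.ci_low > 1.0 or res.ci_high < 1.0):
                    best = (trace + [mod], child)
                    best_depth = depth + 1
                else:
                    stack.append((child, depth + 1, trace + [mod]))
        return best, completed


def _estimate_states(bound: int, n_rails: int) -> int:
    """Upper bound on the number of move multisets of size < ``bound``."""
    return comb(bound - 1 + n_rails, n_rails)


def meta_fragility(
    meta: MetaAnalysisSpec,
    moves: MoveSet = "both",
    exact_nodes: int = DEFAULT_EXACT_NODES,
) -> FragilityResult:
    """Fragility index of a significant pooled meta-analysis.

    Minimal-perturbation search over single-event modifications that move
    the pooled effect toward the null (with ``moves="both"``, additions in
    the null-ward arm and removals in the opposing arm of any trial;
    ``"add-only"`` restricts to additions).  Pooling — including
    re-estimation of tau^2 under the random-effects model — is fully
    recomputed for every state examined.

    Strategy: steepest-ascent greedy and single-rail line searches give an
    upper bound, then a branch-and-bound sweep over all null-ward states
    below that bound certifies or improves it.  The sweep is skipped when
    it would visit more than ``exact_nodes`` states; the returned result
    then has ``exact=False`` and its index is an upper bound.

    Raises
    ------
    NotSignificantError
        If the pooled result is not significant to begin with.
    """
    search = _MetaSearch(meta, moves)
    start_res = search.pool_state(search.start)
    if start_res is None:
        raise InestimableError(
            f"meta-analysis {meta.meta_id!r}: pooled effect inestimable"
        )
    if not search.significant(search.start):
        raise NotSignificantError(
            f"meta-analysis {meta.meta_id!r} is not fragile-indexable: pooled "
            f"CI ({start_res.ci_low:.3f}, {start_res.ci_high:.3f}) includes 1"
        )
    max_steps = sum(t.sample_size for t in meta.trials)
    upper = search.greedy(max_steps)
    rail = search.rail_searches(max_steps)
    if rail is not None and (upper is None or len(rail[0]) < len(upper[0])):
        upper = rail
    if upper is None:
        logger.warning(
            "meta-analysis %r: all search routes saturated while still "
            "significant; not converged", meta.meta_id,
        )
        terminal = search.pool_state(search.start)
        return FragilityResult(
            index=0,
            quotient_pct=0.0,
            trace=(),
            terminal=terminal,
            converged=False,
            exact=False,
        )

    trace, state = upper
    exact = False
    n_rails = (2 if moves == "both" else 1) * len(meta.trials)
    if len(trace) > 1 and _estimate_states(len(trace), n_rails) <= exact_nodes:
        improved, completed = search.branch_and_bound(len(trace), exact_nodes)
        if improved is not None:
            trace, state = improved
        exact = completed
    elif len(trace) <= 1:
        exact = True  # a single modification is trivially minimal

    terminal = search.pool_state(state)
    return FragilityResult(
        index=len(trace),
        quotient_pct=fragility_quotient(len(trace), meta.sample_size),
        trace=tuple(trace),
        terminal=terminal,
        converged=True,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# Exhaustive oracle (small instances)
# ---------------------------------------------------------------------------


def brute_force_meta_fragility(
    meta: MetaAnalysisSpec,
    depth_cap: int = DEFAULT_DEPTH_CAP,
    moves: MoveSet = "both",
) -> FragilityResult:
    """Exhaustive minimal-perturbation search for small meta-analyses.

    Plain breadth-first search over all count-states reachable by
    null-ward single-event modifications, expanding by total modification
    count, so the first non-significant state found has provably minimal
    count.  States are deduplicated (the order of modifications does not
    affect the resulting counts).  Serves as the independent verification
    oracle for :func:`meta_fragility`; restricted to at most 4 trials and
    a depth cap of at most 8.

    Raises
    ------
    FragilitySearchError
        If no non-significant state is reachable within ``depth_cap``.
    """
    if meta.k > 4:
        raise ValueError(f"exhaustive oracle limited to <= 4 trials, got {meta.k}")
    if not (1 <= depth_cap <= DEFAULT_DEPTH_CAP):
        raise ValueError(f"depth_cap must be in [1, {DEFAULT_DEPTH_CAP}], got {depth_cap}")
    search = _MetaSearch(meta, moves)
    if search.pool_state(search.start) is None or not search.significant(search.start):
        raise NotSignificantError(
            f"meta-analysis {meta.meta_id!r} is not fragile-indexable: pooled "
            "result is not significant"
        )
    parent: dict[State, State | None] = {search.start: None}
    edge: dict[State, Modification] = {}
    frontier: list[State] = [search.start]
    for depth in range(1, depth_cap + 1):
        nxt: list[State] = []
        for state in frontier:
            for child, mod in search.children(state):
                if child in parent:
                    continue
                parent[child] = state
                edge[child] = mod
                res = search.pool_state(child)
                if res is None:
                    continue
                if not (res.ci_low > 1.0 or res.ci_high < 1.0):
                    trace: list[Modification] = []
                    node: State | None = child
                    while parent[node] is not None:
                        trace.append(edge[node])
                        node = parent[node]
                    trace.reverse()
                    return FragilityResult(
                        index=depth,
                        quotient_pct=fragility_quotient(depth, meta.sample_size),
                        trace=tuple(trace),
                        terminal=res,
                        converged=True,
                    )
                nxt.append(child)
        frontier = nxt
        if not frontier:
            break
    raise FragilitySearchError(
        f"meta-analysis {meta.meta_id!r}: no non-significant state within "
        f"depth cap {depth_cap}"
    )
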