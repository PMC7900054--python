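# Methods

## Statistical model

Each trial is a 2×2 table: events `a` of `n₁` randomised in the
intervention arm, events `c` of `n₂` in the control arm.  A meta-analysis
is an ordered set of such tables with a pooling configuration (effect
measure RR or OR, fixed- or random-effects model, two-sided level α,
default 0.05).

**Fisher's exact test.**  Two-sided, minimum-likelihood rule: the P value
is the sum of the probabilities of all tables with the observed margins
whose hypergeometric probability is at most that of the observed table.
Probabilities are computed as exact integer binomial coefficients, so the
tie comparison is an exact rational comparison (a relative slack of 1e-7
is applied, matching mainstream implementations, where it absorbs
floating-point noise; here it only matters for the deliberate inclusion of
exact ties) and the returned float is correctly rounded.  A table with no
events anywhere (or events everywhere) admits a single configuration and
returns P = 1.  Mid-P and doubling conventions are not offered.

**Fixed-effect pooling** is Mantel–Haenszel with the Greenland–Robins
variance of the log pooled ratio (both RR and OR variants), robust to
single zero cells without correction.

**Random-effects pooling** is DerSimonian–Laird: per-trial log effects
`y_i` and variances `v_i` from the standard large-sample formulas, the
moment estimator

    τ² = max(0, (Q − (k − 1)) / (Σw − Σw²/Σw)),   w_i = 1/v_i,

with Q Cochran's heterogeneity statistic on the fixed inverse-variance
weights, then pooling with weights `1/(v_i + τ²)`.

In both models the confidence interval is `exp(log_effect ± z_{1−α/2}·se)`
and the P value the two-sided normal tail of `log_effect/se` (plain Wald;
no Knapp–Hartung adjustment).  Significance means the interval excludes 1;
an interval touching 1.0 exactly counts as including the null, the
conservative reading consistent with stopping at "P at least equal to α".
Both engines were verified to 9+ decimals against frozen values from an
independent implementation of the same formulas (R `metafor` 4.8-0).

**Zero cells.**  For inverse-variance and DerSimonian–Laird computations a
trial with any zero cell gets 0.5 added to all four cells; Mantel–Haenszel
sums are left uncorrected.  Trials with zero events in both arms carry no
information about a ratio and are excluded from pooling (`k` reflects
contributing trials) but still count toward the meta-analysis sample size
used by the fragility quotient.  These are standard meta-analytic
conventions; alternative corrections are deliberately out of scope.

## Fragility index

**Single trial (Walsh construction).**  While the two-sided Fisher P is
below α, convert one non-event to an event in the arm currently holding
the smaller number of events (ties go to the intervention arm) and
recompute P.  The index is the number of conversions at the first
P ≥ α.  If the designated arm runs out of non-events the search reports
`converged=False` rather than silently switching arms.  The index is
defined only for significant inputs; a non-significant input raises an
error rather than returning 0.

**Meta-analysis.**  The index is the minimum number of single-event
modifications — each preserving arm sizes — after which the pooled
confidence interval includes 1.  The admissible move set is null-ward:
with a protective pooled effect (below 1), add intervention events or
remove control events in any trial; mirrored for harmful effects.  Since
the index is a minimum over perturbations, the richer move set can only
lower it; `moves="add-only"` restricts to additions for sensitivity
analyses.  Pooling — including re-estimation of τ² under the
random-effects model — is recomputed in full for every candidate state.

The search runs in three stages:

1. *Steepest-ascent greedy*: repeatedly apply the single modification
   whose re-pooled P value is largest (ties broken by trial input order,
   then intervention before control arm, for bit-reproducibility).
2. *Single-rail line searches*: spend the entire budget in one arm of one
   trial; take the best over all 2k rails.
3. *Branch-and-bound refinement*: a depth-first sweep with state
   deduplication over all null-ward states strictly below the best bound
   from stages 1–2, which either certifies that bound as the minimum or
   improves it.

Stage 3 exists because steepest ascent alone is not minimal: adding an
event to a near-empty arm can *lower* the pooled P value — the trial's
variance shrinks faster than its effect moves toward the null — so the
myopic P-maximiser walks around such valleys and can overshoot the true
minimum by several events (e.g. single trial 1/35 vs 21/57, fixed-effect
RR: steepest ascent needs 8 modifications, the minimum is 5).  In
validation against an independent exhaustive breadth-first oracle
(`brute_force_meta_fragility`, plain BFS by modification count over
deduplicated count-states, limited to ≤ 4 trials and depth ≤ 8) the
three-stage search returned the exact minimum on 500/500 random
significant meta-analyses of 1–3 trials under both pooling models.

The refinement is skipped when the state space below the bound (estimated
as C(bound−1+R, R) for R rails) exceeds the `exact_nodes` budget (default
50 000).  The result then carries `exact=False` and is an upper bound on
the true minimum — in practice the better of two strong heuristics.  This
keeps corpus-scale runs fast while keeping small indices, where exactness
matters most, certified.

**Fragility quotient.**  FQ = 100 · FI / N with N the total participants
of all included trials (including any double-zero trials).  Reported in
percent; displayed to two decimals by the CLI, full precision in JSON.

## Corpus statistics

Medians and quartiles use the linear-interpolation quantile convention
(the dominant default in scientific software).  Cumulative curves are the
empirical cumulative counts of meta-analyses at or below each distinct
observed fragility value.  Pearson correlations between fragility measures
and pooled P values use the product-moment formula, a Fisher-z confidence
interval with variance 1/(n−3), and a two-sided P from
`t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom; a constant input is an
error (undefined correlation), not a silent zero.  Correlations are
computed on the raw scale by default with a `log2_scale` switch, since
survey figures sometimes display fragility on a log₂ axis; the choice
changes r but not its sign.

## Synthetic corpus generator

The generator emulates the statistical structure of a survey corpus of
significant meta-analyses; no real corpus of 2×2 tables is bundled, and
the generator makes no attempt to model literature screening or
publication bias.  Per candidate meta-analysis:

* number of trials k ~ Uniform{2..10};
* each arm size ~ round(Lognormal(log 60, 0.6)) clipped to [10, 2000]
  (median 60 participants per arm, right-skewed, as is typical of
  surgical trials);
* control event rate p_c ~ Beta(mean 0.15, concentration 10) clipped to
  [0.01, 0.6];
* a per-meta-analysis true log relative risk ~ Normal(log 0.6, 0.3) — a
  moderately protective average effect, so that a realistic fraction of
  candidates reaches significance;
* per-trial heterogeneity: log RR_i = meta log RR + Normal(0, τ = 0.2),
  the standard additive random-effects generative model, with the implied
  intervention risk capped at 0.99;
* events: Binomial draws per arm.

Candidates are pooled under the configured model (default random-effects
DL on RR) and only those whose pooled interval excludes 1 are retained —
the survey inclusion rule — until the target count (default 79) is
reached; rejected candidates are counted and the run aborts if acceptance
falls below 1/1000.  Seeding uses one master seed with per-candidate child
streams (`SeedSequence(master, spawn_key=(i,))`), so enlarging a corpus
never reshuffles earlier meta-analyses and corpora are byte-reproducible.

With these defaults the seeded corpus 20210116 yields 79 included
meta-analyses with median FI 5 (IQR 2–9, range 1–20), median FQ ≈ 0.6%,
and Pearson r ≈ −0.60 between FI and pooled P — the same order as
published fragility surveys of meta-analysis corpora.  What passing tests
on such corpora do **not** show: anything about the fragility of any real
literature; the generator has no screening funnel, no publication bias, no
correlated outcomes, no non-inferiority designs, and its distributional
defaults are stand-ins chosen once, exposed as `CorpusModel` fields for
re-calibration.

**Two-study contrast.**  A deterministic grid search (equal-arm trials,
arm size 400–1600 by 100, control events by 10, intervention events
spanning risk reductions of 17–23%, keeping Fisher P in [0.015, 0.03])
produced a large trial with a 20% relative risk reduction to pair with the
small 1/100-vs-9/100 trial (89% reduction); both have Fisher P ≈ 0.02, yet
their fragility indices are 1 and 9.  The tables are frozen in
`construct_two_study_contrast`.

## Numerical and design notes

* Exact integer arithmetic in Fisher's test makes the exhaustive-agreement
  check against independent enumeration meaningful at 1e-12.
* Wald significance (CI excluding 1) and P < α agree by construction; the
  equivalence is asserted over 10⁴ random meta-analyses in the tests.
* Under a homogeneous null (true RR 1, τ = 0) the fixed-effect filter's
  empirical type-I rate is ≈ 0.045 at the generator's defaults — the small
  residual conservatism comes from continuity corrections at the
  generator's modest event counts.  The random-effects DL filter is
  markedly more conservative under homogeneity (≈ 0.028): estimating a
  non-negative τ² from homogeneous data inflates interval width, a
  well-known DL property.  The calibration check therefore targets the
  fixed-effect engine, which matches the homogeneous generative null.
* Problem sizes in the test suite (e.g. 500 oracle-equivalence instances,
  200 replicate corpora at reduced trial counts and arm sizes, 150
  significant trials per arm-size level) were chosen to give stable
  verdicts at interactive runtimes; all are parameters of the tests, not
  of the package.
* Reports are pure functions of (input, configuration, seed); a timestamp
  enters the provenance block only when explicitly supplied, so JSON
  reports are byte-identical across reruns by default.

## Known limitations

* The meta-analysis index is certified minimal only within the
  branch-and-bound budget; very robust meta-analyses (large indices)
  receive a heuristic upper bound, flagged via `exact=False`.
* Peto odds ratios, alternative continuity corrections,
  profile-likelihood or REML τ², Knapp–Hartung intervals and prediction
  intervals are out of scope.
* Fragility of non-significant results ("reverse" indices), continuous or
  time-to-event outcomes, and network meta-analyses are out of scope.
* Walsh's single-trial rule modifies only the smaller-event arm; when that
  arm saturates the result is reported as non-converged rather than
  redefined.
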