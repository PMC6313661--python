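# Methods

## Scope and model

`decisio` implements value-based compensatory MCDA for small clinical
decision models: an option's worth is the weighted sum of its criterion
ratings, `S_o = Σ_k w_k r_ok`, with ratings on [0, 1] (1 = best) and
weights normalized to sum to 1. Compensatory means a weakness on one
criterion can be offset by strength on another; non-compensatory schemes
(outranking, lexicographic rules) are deliberately out of scope, as is
probabilistic propagation of rating uncertainty — certainty of evidence
enters only through the level multiplier described below.

Assumptions worth stating plainly: ratings are treated as interval-scale
values comparable across criteria once mapped to [0, 1]; weights express
relative importance of *swings* across that common scale; and the
person's preferences are taken as authoritative — the package computes
opinions, it never issues directives, and every report carries a
disclaimer saying so.

## Certainty adjustment

GRADE grades certainty of evidence per outcome, so multipliers attach to
criteria, not options: both options share `c_k` on criterion `k`. The
default mapping (very low 0.1, low 0.4, moderate 0.7, high 1.0) is a
config default, not a hard-coded constant, because the specific numbers
are debatable even where the principle of numeric mapping is not.
User-sourced practical criteria default to high certainty — the person is
the authority on their own circumstances — and are overridable.

How the multiplier enters the score is genuinely open. The default
`multiplicative` mode, `S'_o = Σ w_k c_k r_ok`, is the most literal
reading of mapping certainty onto the 0–1 scale; because multipliers are
applied per criterion, multiplying ratings and multiplying per-criterion
score contributions are algebraically identical, so nothing hangs on that
distinction. Multiplication, however, asymmetrically penalises *good*
ratings (it drags everything toward 0, i.e. toward "bad"), so a
`shrink_to_neutral` alternative is provided that pulls uncertain ratings
toward the neutral midpoint 0.5: `S'_o = Σ w_k (c_k r_ok + (1−c_k)·0.5)`.
Every report states which mode and mapping produced its numbers, and the
adjusted pair is never renormalized — the unadjusted and adjusted scores
are shown together precisely so the adjustment's effect stays visible.

Scores equal within 1e-9 are reported as ties, never silently ordered.

## Sensitivity analysis

**Flip thresholds.** One-way analysis varies a criterion's normalized
weight `t` over [0, 1] while the other weights keep their baseline
proportions (rescaled to sum to `1 − t`) — the standard normalized
one-way scheme; other co-variation schemes are out of scope. For two
options the score difference is linear in `t`, `D(t) = (1−t)R + t·Δr_j`,
so the flip point is a closed-form zero crossing; a flip is reported only
where the preference actually changes sign on [0, 1]. The closed form is
tested against an independent 0.001-resolution grid scan.

**Preference heterogeneity.** Weight vectors are drawn from a Dirichlet
distribution on the simplex; each is scored and the share of draws
preferring each option recorded, with exact ties split equally so shares
are unbiased under symmetry. The default symmetric Dirichlet(1) (uniform
on the simplex) is a maximally agnostic stand-in for unmeasured
variability in values: the simulator characterises how
preference-sensitive the *decision* is, it does not estimate any real
population's preferences — group-average preferences are explicitly not
the point of person-centred support. Concentration is configurable to
encode tighter consensus. All simulation output is bit-reproducible from
`(n, concentration, seed)`.

**Classification.** The share of simulated informed patients preferring
the best option maps to `strong_for` (≥ 0.9 by default), `weak_for`
(≥ 0.6) or `equipoise`. The verbal notion "most informed patients" has no
agreed numeric boundary, so these defaults are working values, surfaced
in config and in every report that uses them.

## The bundled TAVI/SAVR model

The worked example is built from nine pooled randomized effect
differences (TAVI minus SAVR, harm scale): mortality −3, stroke −2,
acute kidney injury −5, bleeding −24, new-onset atrial fibrillation −18
percentage points and admission −3 days favouring TAVI; heart-failure
symptoms +6, pacemaker +15 and reintervention +1 percentage points
favouring SAVR. The favoured option is *derived* from the stored sign so
data-entry slips are detectable.

Because the evidence reports differences, not absolute performances, a
reference-anchored value function converts them to ratings: SAVR anchors
every evidence criterion at 0.5 and TAVI sits at `0.5 + 0.5·benefit`,
with benefit as a proportion (percentage points / 100; admission days
over a configurable 30-day horizon, a round convalescence window that
keeps a 3-day difference visible but modest). The slope 0.5 keeps the
largest difference (bleeding, 0.24) at rating 0.62, well inside [0, 1];
any clipping is logged. The anchoring is a modelling choice: it preserves
the sign and relative magnitude of every published difference but fixes
the exchange rate between, say, a percentage point of mortality and one
of atrial fibrillation. Users who reject that equivalence should adjust
weights or supply their own value functions.

Editorial defaults, flagged in model metadata: the seven featured
evidence criteria (mortality, stroke, bleeding, atrial fibrillation,
heart failure, pacemaker, reintervention — kidney injury and admission
length re-addable via overrides); the three practical-consideration
labels (avoiding open-heart surgery, burden of recovery, concern about
valve durability), initialised to a neutral 0.5 for both options;
moderate certainty for all evidence criteria. Age group is recorded but
changes the numbers only through explicit effect overrides — age-specific
mortality/stroke estimates exist but are not bundled, and none are
fabricated. Each practical criterion is rated per option (one cell per
option) rather than as a single differential judgment, so the same
machinery serves locked and unlocked criteria. A "do nothing" option is
out of scope for this add-on model.

## Interfaces and numerical choices

Model documents are versioned YAML; unknown fields are rejected rather
than ignored because silent misconfiguration is the worse failure mode in
a clinically-facing tool. Floats round-trip bit-identically (repr-based
serialization). Criterion order is preserved everywhere — no output ever
sorts criteria — so reports are stable and diffable; reports contain no
timestamps and regenerate byte-identically, with run metadata going to
the log instead. A content hash ties score objects to the model state
they were computed from, so a report cannot silently combine a model with
stale scores. Rating updates are immutable (they return a new model),
which makes elicitation sessions replayable and makes the locked-rating
guarantee easy to verify: a failed edit leaves the original bit-identical.
Weights are elicited as raw nonnegative numbers on any convenient scale
(e.g. 0–100 sliders) and normalized internally.

## Testing strategy and problem sizes

Computational routes are verified against independent implementations:
vectorised scoring against an explicit double loop (1,000 random models,
up to 6 options × 12 criteria, agreement to 1e-9), closed-form flip
thresholds against a 0.001 grid scan (200 random two-option models), and
vectorised preference shares against a score-and-count loop (exact).
Simulation checks use n = 10,000 draws, at which the binomial standard
error on a share is 0.005. These sizes make the whole suite run in
seconds while leaving the statistical checks well-powered.

What passing tests show — and don't: the synthetic random models cover
the full structural space of small decision models (dimensions, certainty
levels, rating patterns), so the arithmetic, invariances and
reproducibility are thoroughly exercised. They say nothing about whether
any particular clinical evidence table, anchoring choice or elicited
weight set is *appropriate* — the bundled model's ratings inherit every
limitation of the published pooled estimates and of the reference-anchored
conversion above.

## Known limitations

* Ratings carry no uncertainty beyond the four-level certainty multiplier;
  intervals or distributions on ratings are not propagated.
* The reference-anchored conversion imposes a linear, symmetric exchange
  rate between criteria; no utility curvature is modelled.
* Flip thresholds are one-way only; joint weight perturbations are not
  analysed.
* The preference simulator characterises sensitivity under a chosen
  Dirichlet; it is not an estimate of any real population.
* Two options are assumed by the sensitivity module; scoring itself
  handles any number.
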