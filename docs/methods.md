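# Methods

## Task environment

The stimulus space is the full factorial of four binary tone features
(duration, modulation direction, intensity, frequency range): 16 tones.
The target category is a conjunction on the two task-relevant features
(default short ∧ rising), fixed but configurable; category identity is
symmetric by construction, so nothing depends on which conjunction is
chosen.  A session holds 240 trials; before and at trial 120 targets
require response 1 and non-targets 0, afterwards the mapping is inverted
(a pure relabeling — the invariant `required_post = 1 − required_pre` is
property-tested).  Responses are abstract 1/0 labels with no button
semantics.  No mid-session break is simulated.

The four canonical pseudo-random orders are regenerated from four fixed,
documented seeds under the constraints: each tone exactly 15 times (which
forces exactly 25% targets), exactly 5 targets per 20-trial block, and at
most 3 consecutive targets.  Block-level target balance is an assumption —
the original orders are not published — chosen so that 12-block statistics
are comparable across orders, as in standard pseudo-randomization practice.
Per-trial durations are drawn uniformly from {6, 8, 10} s with the session
seed; they exist solely to advance the simulated clock that the recency
window consumes.  The four sessions are fixed per order and shared by every
batch and configuration.

## Agent

All 64 strategies live in declarative memory from the start; there is no
strategy induction, only search.  The working-memory slot holds exactly one
current strategy.  The control state carries the complexity level
(one-feature vs two-feature), an `error_noted` flag (a trusted strategy
just failed once and is under re-evaluation), and an `env_change` flag.

Feedback processing:

* **positive** — the strategy is kept; its success count increments up to
  the applicable threshold (`first_count` for complexity 1, `second_count`
  for complexity 2), at which point it becomes *often successful*; any
  ongoing re-evaluation ends (`error_noted` cleared).  Counts are capped at
  the threshold and persist in the store across retrieval episodes.
* **negative** — exactly one of six branches applies, ranging from the
  response flip of a never-successful one-feature strategy to the
  environment-change escalation of a repeatedly failing, often-successful
  two-feature strategy.  "Failed repeatedly" means two failures with no
  intervening positive feedback on that strategy: a success during
  re-evaluation clears the error note, because the strategy has just been
  re-evaluated successfully.

Retrieval draws uniformly at random among eligible candidates.  Eligibility
combines the branch's structural constraints (complexity, response,
condition overlap) with two memory filters:

* **recency** — a strategy used within the last `finst_span_s` seconds is
  excluded.  Recency tags mark *use*, not merely the moment of retrieval:
  when a strategy is given up after negative feedback its tag is refreshed,
  since it was in use up to that trial.  An optional `num_finsts` bounds
  the number of tags tracked at once (cognitive architectures typically
  keep a small fixed pool, e.g. four); the default is unbounded, and the
  measured difference between the two settings is small.
* **negative evaluation** — the `failed` flag excludes strategies from the
  *one-feature* search only.  Two-feature switches retrieve "any other"
  recency-eligible strategy; the failed flag is still recorded but does not
  filter two-feature retrieval.  This asymmetry follows the behavioural
  description of the search (the not-negatively-evaluated condition is
  stated for the one-feature level, while two-feature replacement is
  described as a random draw among the others) and also reproduces the
  observed share of non-learner runs better than a symmetric filter.

Degenerate retrievals cannot deadlock: an empty one-feature pool triggers
the level switch to two-feature; an empty two-feature pool clears the
two-feature recency tags and retries (with 48 candidates this is the only
renewal ever needed).  The response-flip branch is a fully constrained
retrieval of the sibling strategy and is exempt from the recency filter.
The level never returns from two-feature to one-feature; one-feature
bookkeeping is frozen once the level switches.

One run seeds a single generator that is consumed in a fixed order (initial
strategy, then retrieval tie-breaks trial by trial), so a run is a pure
function of (configuration, session, seed).

## Simulator and statistics

A batch is 160 runs (40 per order); a sweep is one batch per cell of the
3 × 3 × 2 parameter grid (`first_count` 3/4/5, `second_count` 6/8/10,
`finst_span_s` 80/100 s — 18 configurations).  Per-run seeds derive from
`SeedSequence([master_seed, config_index, run_index])`, so single runs are
reproducible in isolation and results are independent of execution order.

Learning curves aggregate correctness into 12 blocks of 20 trials.  Fit
against the packaged participant curve (12 block means ± SD of 55
participants, stored as CSV in the package data) uses Pearson *r*, *r²*,
and RMSE computed **on the proportion (0–1) scale**; percent-scale input is
rejected with an error because it silently inflates RMSE a hundredfold.
A constant model curve raises a distinct zero-variance error rather than
returning NaN.  Levene's test is the original mean-centred variant,
implemented from the definitional formula (all-identical data return
W = 0, p = 1) and cross-checked against an independent reference
implementation to 1e-9; the participant SDs feed plotting and variance
comparisons only, never *r*/RMSE.  The 85% criterion separates learner from
non-learner runs per block.  Across-run SDs use the n−1 denominator.

## Numerical and design notes

* Retrieval replaces architecture-level activation computations (base-level
  learning, activation noise) with the hard recency window plus uniform
  choice described above: the behavioural ingredients are recency and
  randomness, and this keeps the model assumption-minimal.
* Block arrangement rejects permutations with more than 3 consecutive
  targets (rejection sampling with a generous retry bound; the constraint
  is loose, so rejection is rare).
* The below-criterion fractions of a 160-run batch carry binomial
  Monte-Carlo noise of ≈3.6 percentage points (1 SE); tests on these
  quantities use a two-SE band.
* Manifest-driven outputs are written with fixed float precision so a
  manifest reproduces its files byte-for-byte.

## Known limitations

With uniform retrieval among eligible candidates the strategy search is
more efficient than one weighted by past use: simulated learning starts
above chance in block 1 (≈59% vs ≈50–53% in the published reference
model), dips deeper in the first post-reversal block (≈53% vs ≈62%), and
recovers faster.  The simulated mean curves therefore track the human
learning curve *more* closely (r ≈ 0.93–0.97, RMSE ≈ 0.08–0.09) than the
published reference fits (best r = 0.820, RMSE = 0.109), and the share of
runs below 85% in block 12 runs ≈5–7 points above the published 30%.
Qualitative structure — rise to block 6, sharp reversal dip, recovery,
ordering of parameter settings (lower thresholds fit better), and
across-run variance exceeding the across-participant variance outside the
transition blocks — is reproduced.  Passing tests on the synthetic task
show that the mechanism learns and relearns as described; they do not show
that human listeners share its retrieval statistics, and the generator
abstracts away every perceptual property of the real tones (salience
differences between features, the 10-fold larger human stimulus set,
response deadlines), so no claim about perceptual learning follows.
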