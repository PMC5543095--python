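# revcat

Simulation of rule-based auditory category learning with contingency
reversal, built around a strategy-switching cognitive agent.

## The task and the model

In the modelled experiment, a listener hears one of 16 tones per trial.
Each tone is a combination of four binary features: duration (short/long),
direction of frequency modulation (rising/falling), intensity (low/high),
and frequency range (low/high).  The target category is the conjunction of
two task-relevant features — by default *short* ∧ *rising* — so 4 of the 16
tones (25% of trials) are targets.  The listener responds 1 or 0 on each of
240 trials and receives feedback; after trial 120 the response
contingencies reverse without warning, so everything learned must be
relearned in mirror image.

The agent solves this task by hypothesis testing over *strategies*:
exemplar-like memory records pairing one or two feature–value conditions
with a response.  A strategy answers with its stored response when the tone
matches its condition(s) and with the opposite response otherwise, so each
of the 64 possible strategies (16 one-feature + 48 two-feature) is a
complete classifier.  Learning is a feedback-driven search through this
space, governed by three metacognitive mechanisms:

* **success tracking** — positive feedback keeps the current strategy and
  increments a capped success count; reaching a threshold (`first_count`
  for one-feature, `second_count` for two-feature strategies) marks the
  strategy *often successful*, after which a single failure triggers
  re-evaluation rather than replacement;
* **graded revision after failure** — a fresh one-feature strategy that
  fails immediately flips its response; a partially successful one swaps
  its feature–value pair but keeps its response; a partially successful
  two-feature strategy is replaced by one sharing a condition and the
  response; repeated failure of an often-successful strategy escalates
  (one-feature → switch to two-feature level; two-feature → note an
  environment change and restart the search);
* **recency-constrained retrieval** — strategies used within the last
  `finst_span_s` simulated seconds (≈10–12 trials at the 6/8/10 s trial
  durations) are excluded from retrieval; the choice among the remaining
  eligible candidates is uniform at random.

Model fit is evaluated on the mean learning curve over 12 blocks of 20
trials: Pearson *r* / *r²* (relative fit) and RMSE on the proportion scale
(absolute fit) against the packaged reference curve of 55 human
participants, plus Levene's test for comparing across-run with
across-participant variance, and the share of runs below the 85%
learning criterion.

## Worked example

A single simulated session (the command prints one line per 20-trial
block):

```
$ revcat simulate --seed 4 --order 1
config 3_06_100, order 1, seed 4
  block  1:  70.0% correct
  block  2:  70.0% correct
  block  3:  55.0% correct
  ...
  block  7:  70.0% correct
  block  8: 100.0% correct
  block 12: 100.0% correct
  overall:  76.7% correct
```

This run churns through strategies for five blocks (near-chance stretches
like blocks 5–6 are failed two-feature hypotheses), is mid-search when the
reversal hits, and then locks onto the correct post-reversal conjunction
from block 8 on — a typical "late learner" trajectory.  Add `--log
trials.csv` to see the strategy held, the response, and the bookkeeping on
every trial.

A full batch of one configuration — 160 runs, 40 per pseudo-random order —
and its fit to the participant curve:

```
$ revcat batch --runs 160 --seed 1 --out out/
config 3_06_100: r=0.961 r2=0.923 rmse=0.087
```

Here *r* is the Pearson correlation between the 12 mean block proportions
of the batch and the participants' block means, and the RMSE of 0.087 says
the simulated curve sits on average about 9 percentage points from the
human curve (the agent underperforms people early in each phase).  The
command also writes tidy per-run and per-block CSVs plus a JSON metadata
record; `revcat sweep` does the same for the full 18-cell parameter grid
(`first_count` 3/4/5 × `second_count` 6/8/10 × `finst_span_s` 80/100), and
`revcat report` recomputes the fit table from the per-run CSV.

Python API equivalent:

```python
from revcat import ModelConfig, run_batch, fit_statistics, PARTICIPANT_CURVE

batch = run_batch(ModelConfig(3, 6, 100.0), n_runs=160, master_seed=1)
print(fit_statistics(batch.block_means, PARTICIPANT_CURVE))
```

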