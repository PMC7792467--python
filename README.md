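# wmdec

A discrete-cycle simulator of a multi-store working-memory architecture
with *distributed* executive control: instead of a central executive, task
control emerges from learned condition-action rules operating over four
limited-capacity stores — an episodic buffer, a phonological loop, a
visuospatial store and an executive memory holding task sets — embedded
between sensory registers and a motor system.  The package is for
researchers in cognitive modelling who want to simulate task switching,
dual-task coordination and memory span within one mechanistic model, and
to reproduce the published simulation studies of those paradigms.

## The model in brief

Time is sliced into 10-ms cycles.  Each cycle runs a fixed twelve-step
procedural loop (decay and capacity enforcement, maintenance operations,
response-tendency accumulation, stochastic access flags, gaze, sensory
update, rule matching — one rule selected per cycle — and response
delivery).  The core quantitative laws, per cycle:

- activation growth `a(t+1) = a(t) + (1 − a(t))·α` (creation, refreshment,
  consolidation with κ, rehearsal/revival with ρ);
- multiplicative decay/inhibition `a(t+1) = a(t)·δ` (phonological δ,
  visual σ, lateral inhibition β, rejection τ);
- two-step capacity rescaling when Σa exceeds C (2.9 in the buffer, 5.0 in
  executive memory): earlier-episode and discarded traces pay first, then
  everyone;
- rule learning `s ← s + (1−s)·η` after success, `s ← s·(1−η)` after
  failure (η = 0.00008), plus creation of direct stimulus-response rules
  (strength 0.05);
- response selection as a race of noisy accumulators gaining `λ·r + ζ`
  per cycle until the threshold θ (0.40-0.60, adapted by feedback).

Statistical subjects resample α, β, φ, τ, θ and ζ from clipped gaussians
(`v = r(h−l)/6 + m`).  See `docs/methods.md` for the complete account.

## Worked example

Simulate two statistical subjects of the cued task-switching study
(3 tasks x 16 digit/digit-word targets x 10 cue-target intervals):

```python
from wmdec import experiments as xp
from wmdec.analysis import rt_summary

design = xp.build_study1()
df = xp.run_study1(design, seed=7, n_subjects=2, trials_per_subject=240)
print(rt_summary(df[df.transition != "first"], ["transition"])
      [["transition", "rt_ms", "accuracy"]])
```

prints (seed 7):

```
  transition       rt_ms  accuracy
0     repeat  788.625000  0.993789
1     switch  862.345277  0.968454
```

i.e. task repetitions are answered roughly 74 ms faster than task
switches, with fewer errors — repeating a task reuses the goal and
task set still present in working memory, while a switch must inhibit the
old goal, rebuild the new one and re-configure its task set after the
target appears.

A single trial can be replayed with a full cycle-by-cycle event log:

```
wmdec trace --seed 3 --cti 900
```

which shows the narrated processing chain (cue instance, goal, task set,
categorisation, bind, response execution, response emission) with the
cycle each event occurred.

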