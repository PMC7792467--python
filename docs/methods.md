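# Methods

`wmdec` simulates a multi-store working-memory architecture in which
executive control is not a central agent but a collection of learned
condition-action rules operating over limited-capacity stores.  This note
describes the model as implemented, the parameters that matter, the choices
made where the design was genuinely open, and what the packaged simulations
do and do not show.

## The architecture

**Declarative long-term memory (dLTM)** is a labelled graph.  Nodes carry a
name, a syllable count (verbal items) and a fixed strength of 0.50; links
are superordinate/subordinate (mirrored automatically on load), property,
opposition (symmetric) and sequence.  Opposition links drive lateral
inhibition between competing cues, goals and task sets.

**Procedural long-term memory** is a set of production rules in a small
text DSL (`IF term AND term ... THEN action(args)`, `!` negation, `X=`
binding).  Conditions are evaluated left to right with single-pass variable
binding — there is deliberately no general unification.  Every rule has a
strength in [0, 1] and a duration in cycles.  After each trial the rules
selected during that episode are strengthened
(`s + (1-s)·eta`) or weakened (`s·(1-eta)`, eta = 0.00008) depending on the
outcome, and a successful stimulus–response pairing spawns a direct
association rule (strength 0.05, duration 5) that feeds the automatic
response stream.

**Working memory** comprises four stores plus an episodic long-term store:

- *Episodic buffer (EB)*: rich multimodal traces (goals, cues, objects,
  classes, responses, chunks, binds).  Creating a trace takes `20 + 4r`
  cycles (Gaussian r, floored at 1 cycle); during creation activation grows
  from phi = 0.25 by `a + (1-a)·alpha` per cycle, and opposed traces
  inhibit each other multiplicatively (beta = 0.99 per cycle).  Completed
  traces do not decay; they are lost through capacity competition.  When
  the summed activation exceeds C = 2.9 a two-step rescaling applies:
  first only traces from earlier episodes or discarded ones pay, then, if
  the total still exceeds C, everything is rescaled.
- *Phonological loop*: a circular list of verbal traces decaying at
  delta = 0.989 per 10-ms cycle, counteracted by rehearsal
  (`d = 0.9·sqrt(n)·t_s + r` cycles per item, growth rate rho = 0.10).
  Note the parameter as printed gives a half-life of roughly 0.6 s, not
  the 2 s stated alongside it; the printed value is kept.
- *Visuospatial store*: grid-bound traces decaying at sigma = 0.99,
  counteracted by revival (`d = 25 + r`).
- *Executive memory (EM)*: task sets (parameters, category-response
  mappings, actions) under a shared capacity of 5.0 that counts the task
  sets' activations plus a fixed load of 0.2 per uploaded component, so
  juggling several configured sets saturates the store.
- *Episodic LTM*: a trace consolidates by `s + (1-s)·kappa`
  (kappa = 0.001) on every cycle its EB source is being refreshed; at
  recall it is tried once after repeated buffer failures and succeeds when
  `s >= 0.5·r`.

**Access** is stochastic and fixed within a cycle: one fresh uniform draw
per store; phonological traces are open when `a >= (0.6 r)^2`, all other
stores use a step rule (always open above 0.5, else open when
`a >= 0.5 r`).

**Perception and action.**  Visual events land in a 9x9 iconic store with
NEW/CHANGE/FADE/GONE flags; only the fixated cell and its eight neighbours
are readable.  Events outside that area trigger a saccade of 3-6 cycles
(`clamp(2 + distance, 3, 6)`) during which no visual change registers.
After `20 + 3r` cycles of fixation the gaze drifts one cell at random,
tethered to the display region where events occur.  Responses race as
noisy accumulators gaining `lambda·r + zeta` per cycle (intentional stream
zeta = 0.015, automatic 0.004); the first across the threshold theta wins,
intentional streams win ties, and emissions while the motor system is
blocked are suppressed.  Speed-accuracy control lowers theta by 0.01 after
five consecutive correct responses and raises it by 0.02 after an error,
within [0.40, 0.60].

**The procedural loop** executes twelve ordered steps per 10-ms cycle
(stage response; decay and capacity; rehearsal; revival; consolidation;
tendency increments; access flags; gaze; sensory update; flag sync; rule
matching and selection; response delivery).  One rule at most is selected
per cycle — highest strength wins, ties break uniformly at random.  A
duration-d rule selected at cycle c completes (and its action applies) at
c + d - 1; actions whose object is busy wait FIFO for the lock and then
run their full duration.

## Parameters

Table defaults: alpha 0.02, beta 0.99, phi 0.25, tau 0.75, C_EB 2.9,
C_EM 5.0, delta 0.989, rho 0.10, sigma 0.99, eta 0.00008, kappa 0.001,
theta 0.50, lambda 0.01, zeta 0.015/0.004, syllable 50 cycles, cycle
10 ms.  Statistical subjects resample alpha, beta, phi, tau, theta and
zeta as `v = r(h-l)/6 + m` clipped to [l, h].

Implementation-level settings (exposed on `ModelParameters`):

- `refresh_dwell` = 2 cycles per refresh act plus 1 switching cycle.  Not
  printed anywhere; chosen so that solo refreshment takes a trace from
  0.25 to ~0.52 in 67 cycles, matching the narrated trajectory (band
  0.50-0.62).
- `recreate_mean` = 7 cycles: re-creating a recently discarded trace is
  faster than building a new one, and the trace resumes part-built — its
  starting activation is set so it completes at the level a full creation
  reaches (~0.50).  Renewing a trace that is still present (same trace,
  new episode) costs half of that.
- `access_retry` = 4 cycles between retrieval attempts,
  `max_item_failures` = 3; a failed retrieval access is a rejection and
  inhibits the candidate by tau.
- `prune_floor` = 0.10: traces switched OFF (inhibited or already
  recalled) linger and hold capacity until the squeeze grinds them below
  this; traces flagged DONE at trial cleanup are dropped immediately so
  the next episode's instances grow into freed slack.

## Rule sets

The deposited rule inventories are not printed, so the rule sets shipped
under `wmdec/rulesets/` are re-authored from the two worked examples and
the documented condition vocabulary.  They are plain-text data: the task
variants (hierarchical vs combined task sets, chunking levels,
colour-cued switching) differ only in which files and declarative
fragments are loaded.  Durations and strengths were calibrated against
the narrated single-trial event sequences (cue at cycle 50, response
registered near cycle 231 on an unprepared trial) and the published
simulated mean RTs; they are the model's open degree of freedom and are
part of these fixtures, not of the engine.

Design choices embodied in the rules (each is a modelling claim, not
plumbing):

- Task-set engagement is gated on the trial's cue (or, in colour-cued and
  task-span contexts, on the governing goal) plus target presence, so
  configuration completes only after the target — the source of the
  residual switch cost.  Displacing a task set clears its uploaded
  mappings; they are re-uploaded one mapping per rule firing.
- A repeated goal is renewed (cheap re-creation into the current episode)
  rather than rebuilt; an opposed goal is inhibited by tau when its
  competitor's cue or colour appears.
- The cue, and the object/class traces once the bind holds the response,
  are released (inhibited) when no longer needed, freeing buffer capacity.
- Each memorandum presentation opens a new episode, so earlier list items
  lose capacity protection against the trace currently being built —
  the primacy-side loss under load.
- Spoken recall instantiates each response in the buffer while it is
  articulated, and retrieval re-activates the memorisation goal; both
  compete with the traces still awaiting recall.
- Dual-task coordination (a COORD instance held active through the trial)
  suppresses task-set displacement and puts refreshment on hold while an
  embedded judgment is unanswered.

## The five simulations

1. **Cued task switching** (3 tasks x 16 digit/digit-word targets x 10
   cue-target intervals, 480 trials per subject).  Switch costs arise from
   goal re-creation under lateral inhibition plus task-set re-engagement
   and re-configuration after the target; preparation absorbs the goal
   stage, leaving a small residual cost.
2. **Task and dimension switching** (digits and number words shown
   simultaneously; number stimuli are implemented as number words at a
   distinct location).  The hierarchical variant treats the attended
   dimension as a task-set parameter (cheap to change); the combined
   variant gives each task-dimension combination its own goal and task
   set, reproducing the flat any-change cost structure.
3. **Complex span under load** (letters followed by 4/6/8 parity or
   location judgments at the stated on/off times).  Spatial judgments
   read the represented position directly (1-cycle categorisation);
   semantic judgments take a 4-cycle declarative lookup, so parity
   occupies more of the interval and recall suffers more.
4. **Memory span vs task span** (ordered task-name lists, recall alone or
   alternating recall with execution; chunking disabled or limited to
   two- or three-item chunks run as separate model variants).  Span is
   estimated as the 0.5 crossing of the proportion of completely correct
   lists.
5. **Switching inside serial recall** (strictly timed colour-cued digit
   lists between letters, or after the whole list in the Brown-Peterson
   variant; the response threshold starts at the low bound 0.40).  More
   switches occupy more of each 1.2-s slot, postponing refreshment.

Complex-span scoring: the span reported for study 3 is the sum over list
lengths 1-7 of the fraction of series reproduced fully correctly (maximum
7) — the standard scoring for this paradigm; a plain mean of
correct-in-position counts over these lengths could not exceed 4 and
cannot express the published span range.

## Problem sizes

The packaged test suite and the acceptance script run reduced designs,
chosen as the package's own desk scale: 8-16 statistical subjects for task
switching (full 480-trial sessions), 3-5 subjects per cell for complex
span, 6-16 subjects and 16-24 study-test sequences per subject for the
span studies, and 8-12 subjects for the strictly timed recall
experiments.  Quantitative checks use +/- 2 SEM of the replication's own
between-subject variation.

## What the simulations do and do not show

The synthetic environments implement the published designs: symbolic
stimuli at grid positions with the stated onsets and durations.  They do
not model stimulus legibility, masking (the masked block of the source
switching experiment is excluded), response-device mechanics, fatigue or
strategic variation beyond the modelled speed-accuracy control; the
phonological loop and visuospatial store are exercised by unit tests but,
as in the published runs, no packaged simulation recruits them.  Passing
tests therefore show that the control architecture reproduces the
relative costs of switching, coordination and load — not that the model
captures any individual participant's strategy.

## Known limitations

- The printed phonological decay rate is kept although it contradicts the
  stated half-life (see above).
- Accuracy effects are coarser than RT effects: errors arise from
  old-task categorisation near a switch and from associative capture, and
  their rates were not separately calibrated.
- The Study-5 switch-frequency contrast (few vs many switches) is small,
  as in the published tables, and at reduced subject counts its sign can
  fluctuate from seed to seed.
- Whether step-2 capacity enforcement precedes that cycle's growth is
  unspecified in the source; enforcement is applied once per cycle at the
  decay step, as listed.
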