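# Fixed embedded judgment task (no cue, no colour cue): a new target
# re-engages the standing judgment goal kept alive by dual-task
# coordination.

RULE goal-reuse strength=0.96 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND G = anytaskgoal() AND oldepisode(G)
  THEN renew(G)
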