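# Colour-cued task selection (embedded digit tasks): a red digit calls for
# the magnitude goal, a blue digit for the parity goal.  The opposed goal is
# inhibited first so the new goal governs categorisation.

RULE col-goal-mag strength=0.96 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == RED AND !ineb(MAG, GOAL, ANY)
  THEN mkgoal(MAG)

RULE col-goal-par strength=0.96 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == BLUE AND !ineb(PAR, GOAL, ANY)
  THEN mkgoal(PAR)

RULE col-demote-par strength=0.95 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == RED AND H = ineb_opp(MAG, GOAL)
  THEN inhibit(H)

RULE col-demote-mag strength=0.95 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == BLUE AND H = ineb_opp(PAR, GOAL)
  THEN inhibit(H)

RULE col-renew-mag strength=0.95 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == RED AND ineb(MAG, GOAL, ON) AND oldepisode(MAG)
  THEN renew(MAG)

RULE col-renew-par strength=0.95 duration=1:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND objcolour(X) == BLUE AND ineb(PAR, GOAL, ON) AND oldepisode(PAR)
  THEN renew(PAR)

# No cue object exists in colour-cued lists; the goal itself licenses
# (re-)engagement of its task set.
RULE col-ts-load strength=0.90 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND !inem(T) AND objpresent(TARGET)
  THEN loadts(T)
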