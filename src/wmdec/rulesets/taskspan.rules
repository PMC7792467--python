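# Task-span recall phase: after recalling the next task name, load the
# corresponding goal and apply that task to the waiting target.

RULE tspan-goal strength=0.93 duration=2:
  IF recallheld() AND X = lastrecall() AND G = ltmprop(X, GOAL) AND !ineb(G, GOAL, ANY) AND objpresent(TARGET)
  THEN mkgoal(G)

RULE tspan-demote strength=0.92 duration=1:
  IF recallheld() AND X = lastrecall() AND G = ltmprop(X, GOAL) AND H = ineb_opp(G, GOAL)
  THEN inhibit(H)

RULE tspan-renew strength=0.91 duration=1:
  IF recallheld() AND X = lastrecall() AND G = ltmprop(X, GOAL) AND ineb(G, GOAL, ON) AND oldepisode(G)
  THEN renew(G)

RULE tspan-ts-load strength=0.90 duration=2:
  IF recallheld() AND G = taskgoal() AND T = ltmprop(G, TSKSET) AND !inem(T) AND objpresent(TARGET)
  THEN loadts(T)
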