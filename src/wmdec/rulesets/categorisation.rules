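# Cued categorisation task family: cue encoding, goal loading, task-set
# configuration, categorisation, mapping, binding, response execution and
# trial-end learning.  Durations are in 10-ms cycles and were calibrated
# against the narrated single-trial event sequence (cue at c50, response
# registered around c231 on an unprepared switch trial).

RULE pcv-cue strength=0.95 duration=2:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, CUE) AND !ineb(X, CUE, ANY)
  THEN mkinst(X, CUE)

RULE pcv-obj strength=0.94 duration=2:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, TARGET) AND !ineb(X, OBJECT, ANY)
  THEN mkinst(X, OBJECT)

RULE goal-load strength=0.90 duration=2:
  IF X = ebacc(ANY, CUE, ON) AND G = ltmprop(X, GOAL) AND !ineb(G, GOAL, ANY)
  THEN mkgoal(G)

RULE goal-renew strength=0.90 duration=1:
  IF X = ebacc(ANY, CUE, ON) AND G = ltmprop(X, GOAL) AND ineb(G, GOAL, ON) AND oldepisode(G)
  THEN renew(G)

RULE goal-demote strength=0.915 duration=1:
  IF X = ebacc(ANY, CUE, ON) AND G = ltmprop(X, GOAL) AND H = ineb_opp(G, GOAL)
  THEN inhibit(H)

RULE ts-load strength=0.90 duration=2:
  IF X = ebacc(ANY, CUE, ON) AND G = taskgoal() AND T = ltmprop(G, TSKSET) AND !inem(T) AND objpresent(TARGET)
  THEN loadts(T)

RULE ts-demote strength=0.88 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND U = inem_opp(T) AND !coord(ANY)
  THEN demts(U)

RULE ts-boost strength=0.87 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND inem(T) AND U = inem_opp(T) AND domts() == U
  THEN boostts(T)

RULE ts-map strength=0.87 duration=8:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND inem(T) AND !tshasmaps(T)
  THEN addmaps(T)

RULE motor-init strength=0.86 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND tspar(T, RSPMOD) != NONE AND gamsget(STATUS) == NONE
  THEN motorinit(T)

RULE motor-unblock strength=0.85 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND tsacc(T) AND gamsget(STATUS) == BLOCKED AND ineb(ANY, OBJECT, ON)
  THEN unblock()

# Semantic categorisation (magnitude/parity/form): a declarative-memory
# lookup.  Spatial categorisation has its own faster rule (location.rules).
RULE categorise strength=0.90 duration=5:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND !tsloc(T) AND tsacc(T) AND tshasmaps(T) AND X = taskobj(T) AND C = classof(T, X) AND !ineb(C, CLASS, ANY)
  THEN mkinst(C, CLASS)

RULE map-resp strength=0.89 duration=3:
  IF C = ebacc(ANY, CLASS, ON) AND G = taskgoal() AND T = ltmprop(G, TSKSET) AND R = mapof(T, C) AND !ineb(R, RESPONSE, ANY)
  THEN mkinst(R, RESPONSE)

RULE bind strength=0.84 duration=2:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND X = taskobj(T) AND C = ebacc(ANY, CLASS, ON) AND !ineb(ANY, BIND, ANY)
  THEN mkbind(G, X, C)

RULE bind-resp strength=0.83 duration=1:
  IF B = bindacc() AND R = ebacc(ANY, RESPONSE, ON) AND !bindhas(RESPONSE)
  THEN addbind(R)

RULE exec-response strength=0.92 duration=1:
  IF B = bindacc() AND bindhas(RESPONSE) AND gamsget(STATUS) == UNBLOCK AND R = bindresp() AND !stream(intentional)
  THEN execute(R)

# Once the task set is engaged and the target is in hand, the cue trace has
# served its purpose; releasing it frees episodic-buffer capacity.
RULE cue-release strength=0.82 duration=1:
  IF X = ebacc(ANY, CUE, ON) AND G = taskgoal() AND T = ltmprop(G, TSKSET) AND tsacc(T) AND tshasmaps(T)
  THEN inhibit(X)

# With the response bound, the object and class traces are no longer
# needed and are inhibited (the bind keeps references to them).
RULE obj-release strength=0.81 duration=1:
  IF B = bindacc() AND bindhas(RESPONSE) AND X = ebacc(ANY, OBJECT, ON)
  THEN inhibit(X)

RULE class-release strength=0.81 duration=1:
  IF B = bindacc() AND bindhas(RESPONSE) AND C = ebacc(ANY, CLASS, ON)
  THEN inhibit(C)

RULE auto-response strength=0.80 duration=1:
  IF R = ebacc(ANY, RESPONSE, ON) AND gamsget(STATUS) == UNBLOCK AND !stream(automatic)
  THEN do(R)

# Trial-end housekeeping runs as ordinary rule firings over consecutive
# cycles: strength learning, association-rule creation, response inhibition,
# feedback removal, bind disintegration.
RULE lrn-strength strength=0.99 duration=2:
  IF feedback(ANY) AND learnstage(0)
  THEN learnstrengths()

RULE lrn-assoc strength=0.98 duration=2:
  IF feedback(ANY) AND learnstage(1)
  THEN learnassoc()

RULE lrn-inhibit strength=0.97 duration=2:
  IF feedback(ANY) AND learnstage(2)
  THEN inhibitresponse()

RULE lrn-clear strength=0.96 duration=2:
  IF feedback(ANY) AND learnstage(3)
  THEN clearfeedback()

RULE lrn-disband strength=0.95 duration=4:
  IF learnstage(4)
  THEN disband()
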