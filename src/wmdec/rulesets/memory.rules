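# Memorisation / serial-recall task family: memory cue and goal, memory
# task set with its six parameters, refreshment action, chunk formation,
# recall cue and retrieval action.

RULE mem-cue strength=0.95 duration=2:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, MEMCUE) AND !ineb(X, CUE, ANY)
  THEN mkinst(X, CUE)

RULE mem-goal strength=0.90 duration=2:
  IF X = ebacc(CMEM, CUE, ON) AND G = ltmprop(X, GOAL) AND !ineb(G, GOAL, ANY)
  THEN mkgoal(G)

RULE mem-ts strength=0.90 duration=2:
  IF G = ebacc(MEM, GOAL, ON) AND !inem(MEMTS)
  THEN loadts(MEMTS)

RULE mem-maint strength=0.88 duration=3:
  IF tsacc(MEMTS) AND tspar(MEMTS, MAINT) == NORF
  THEN setpar(MEMTS, MAINT, RF)

RULE mem-rfact strength=0.87 duration=4:
  IF tspar(MEMTS, MAINT) == RF AND !hasact(MEMTS, REFRESH)
  THEN loadact(MEMTS, REFRESH)

# No duplicate guard: the same symbol may recur later in a list and each
# presentation gets its own trace (attending the stimulus marks it seen).
RULE memorise strength=0.94 duration=2:
  IF inem(MEMTS) AND newcnt(ISM) >= 1 AND X = isnew(ISM, MEMITEM)
  THEN mkmemo(X)

RULE chunk strength=0.86 duration=3:
  IF inem(MEMTS) AND canchunk()
  THEN formchunk()

RULE recall-cue strength=0.95 duration=2:
  IF newcnt(ISM) >= 1 AND X = isnew(ISM, RCLCUE) AND !ineb(X, CUE, ANY)
  THEN mkinst(X, CUE)

RULE recall-on strength=0.91 duration=2:
  IF X = ebacc(CRCL, CUE, ON) AND tspar(MEMTS, RECALL) == OFF
  THEN setpar(MEMTS, RECALL, ON)

# Retrieval is goal-directed: the memorisation goal is re-activated to
# drive recall, and competes for buffer capacity while doing so.
RULE recall-goal strength=0.92 duration=1:
  IF X = ebacc(CRCL, CUE, ON) AND ineb(MEM, GOAL, ON) AND oldepisode(MEM)
  THEN renew(MEM)

RULE recall-act strength=0.90 duration=8:
  IF tspar(MEMTS, RECALL) == ON AND !hasact(MEMTS, RETRIEVE)
  THEN loadact(MEMTS, RETRIEVE)
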