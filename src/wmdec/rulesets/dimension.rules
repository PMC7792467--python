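# Hierarchical task-set organisation: the attended stimulus dimension is a
# task-set parameter set from the cue; changing only the dimension is a
# cheap parameter update rather than a task-set change.

RULE ts-dim strength=0.91 duration=3:
  IF X = ebacc(ANY, CUE, ON) AND D = ltmprop(X, DIMCLS) AND G = taskgoal() AND T = ltmprop(G, TSKSET) AND inem(T) AND tspar(T, DIM) != D
  THEN setpar(T, DIM, D)
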