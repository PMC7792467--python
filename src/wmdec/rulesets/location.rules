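# Spatial categorisation: the judgment (above/below the display centre) is
# read directly off the represented position, without a declarative lookup,
# so the rule is much shorter than semantic categorisation.

RULE categorise-loc strength=0.90 duration=1:
  IF G = taskgoal() AND T = ltmprop(G, TSKSET) AND tsloc(T) AND tsacc(T) AND tshasmaps(T) AND X = taskobj_loc(T) AND C = classof(T, X) AND !ineb(C, CLASS, ANY)
  THEN mkinst(C, CLASS)
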