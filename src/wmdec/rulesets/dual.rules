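# Dual-task coordination: while a COORD instance is active, processing an
# embedded judgment trial puts attentional refreshment on hold; it resumes
# as soon as the judgment is answered.

RULE dual-hold strength=0.96 duration=1:
  IF coord(ANY) AND rfon() AND taskopen()
  THEN holdrf()

RULE dual-resume strength=0.96 duration=1:
  IF rfheld() AND !taskopen()
  THEN resumerf()
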