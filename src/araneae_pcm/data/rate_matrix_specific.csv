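# Constrained rate matrix for Specific foraging strategy (nine states on
# the study's 1-5.5 scale). SYNTHETIC RECONSTRUCTION: the study's
# supplementary matrix is not reproduced in the available text. Built from
# its stated rationale: web architectures interchange among themselves
# (adjacent on the scale), hunting modes interchange among themselves, and
# the web-to-hunting transition is one-way (webs are lost, not regained;
# Dollo, as for the binary Strategy variable).
state,sit_wait,ambush,sit_pursue,stalking,active,sheet_web,funnel_web,orb_web,tangle_web
sit_wait,-,1,1,0,0,0,0,0,0
ambush,1,-,1,0,0,0,0,0,0
sit_pursue,1,1,-,1,0,0,0,0,0
stalking,0,0,1,-,1,0,0,0,0
active,0,0,0,1,-,0,0,0,0
sheet_web,0,0,0,0,1,-,1,0,0
funnel_web,0,0,1,0,1,1,-,1,0
orb_web,0,0,0,1,0,1,1,-,1
tangle_web,0,0,0,0,0,0,0,1,-
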