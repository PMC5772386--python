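# Constrained rate matrix for Silk (main silk type used; five states on
# the study's 1-4 scale). SYNTHETIC RECONSTRUCTION: the study's
# supplementary matrix is not reproduced in the available text. Built from
# its stated rationale: cribellate silk is plesiomorphic and metabolically
# costly, so lineages move away from it (to viscous orb silk or to simpler
# aciniform/dragline use) without regaining it (Dollo).
state,none_dragline,burrow,aciniform_sheet,cribellate,viscous
none_dragline,-,1,0,0,0
burrow,1,-,0,0,0
aciniform_sheet,1,1,-,0,0
cribellate,0,0,1,-,1
viscous,1,0,0,0,-
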