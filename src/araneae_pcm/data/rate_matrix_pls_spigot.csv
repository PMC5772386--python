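# Constrained substitution rate matrix for the singular PLS spigots
# (printed evolutionary rate matrix). Rows are the from-state, columns the
# to-state; 1 = allowed (single shared rate), 0 = forbidden. Loss is
# absorbing; Dollo-style constraints forbid re-evolving lost structures.
state,Flagelliform,Loss,Modified,None,Pseudoflagelliform
Flagelliform,-,1,0,0,0
Loss,0,-,0,0,0
Modified,1,1,-,1,1
None,1,0,1,-,1
Pseudoflagelliform,1,1,0,0,-
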