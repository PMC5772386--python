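# Constrained rate matrix for foraging Strategy (web -> no-web).
# Reconstruction of the study's supplementary matrix from its stated
# rationale: web building is lost, not regained (Dollo), so the reverse
# transition is forbidden. Validated against the study's printed Strategy
# ACE results (root Web likelihood 1.0).
state,Web,NoWeb
Web,-,1
NoWeb,0,-
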