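# Constrained rate matrix for Type (variety of spigot types possessed).
# SYNTHETIC RECONSTRUCTION: the study's supplementary matrix is not
# reproduced in the available text. States follow the study's 1-4 score
# scale plus the cribellum+paracribellar state (no pseudoflagelliform) its
# results discuss for the deeper cribellate taxa. Cribellum-bearing states
# interchange; losses of cribellum, modified spigots or triad spigots are
# one-way (Dollo); the viscous triad arises from cribellate ancestors.
state,std7,std7_mspi,std7_ms,std7_ms_flank_crib,std7_ag_fl,std7_crib_para_pf,crib_para
std7,-,1,0,0,0,0,0
std7_mspi,1,-,0,0,0,0,0
std7_ms,1,0,-,0,0,0,0
std7_ms_flank_crib,0,0,1,-,0,0,1
std7_ag_fl,1,0,0,0,-,0,0
std7_crib_para_pf,0,0,0,1,1,-,1
crib_para,1,0,1,1,1,1,-
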