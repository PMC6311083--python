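# Mucus-production switch of Pseudomonas aeruginosa.
# x = ALGU (sigma factor, levels 0..2), y = anti-ALGU inhibitor (Boolean).
# Thresholds and observation texts are reconstructions from the published
# network diagram; see the package fixtures module.
VAR
x = 0..2 ;
y = 0..1 ;

REG
x [2] -> + x ;
x [1] -> + y ;
y [1] -> - x ;

CTL
# normal response: from the resting state, x never over-expresses
(x=0 & y=0) -> AG(!(x=2)) ;
# pathogenic response: the over-expressed state is stable
(x=2 & y=1) -> AG(x=2) ;
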