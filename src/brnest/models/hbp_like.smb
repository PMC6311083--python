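# Synthetic 9-entity Boolean stand-in for the hexosamine biosynthetic
# pathway (HBP) intersection with PI3K-mTOR-Myc and P53-MDM2 signaling.
# Entity order fixes the state notation (NFkB,P21,FoXM1,PI3K,P53,MDM2,OGT,OGA,CMyc).
# Topology is a documented stand-in containing the attested motifs
# (P53-MDM2 negative feedback, CMyc->OGT, OGA-|OGT, OGT-CMyc loop);
# it does not reproduce any deposited model.
VAR
NFkB = 0..1 ;
P21 = 0..1 ;
FoXM1 = 0..1 ;
PI3K = 0..1 ;
P53 = 0..1 ;
MDM2 = 0..1 ;
OGT = 0..1 ;
OGA = 0..1 ;
CMyc = 0..1 ;

REG
P53 [1] -> + MDM2 ;
MDM2 [1] -> - P53 ;
CMyc [1] -> + OGT ;
OGA [1] -> - OGT ;
OGT [1] -> + CMyc ;
OGT [1] -> + FoXM1 ;
FoXM1 [1] -> - P21 ;
P53 [1] -> + P21 ;
PI3K [1] -> + CMyc ;
PI3K [1] -> + NFkB ;
NFkB [1] -> - P53 ;

CTL
# a stable state with high oncogenic expression is reachable from
# hyper-O-GlcNAcylation onset
(OGT=1,OGA=0) -> EF(AG(OGT=1,OGA=0,PI3K=1,FoXM1=1,P21=0,CMyc=1)) ;
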