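environment_label,field,value,provenance
C(-CH3),Lipo,-0.6327,anchor
C(-CH2-),Lipo,-0.3998,anchor
C(-CH2-OH),Lipo,-0.9463,anchor
O_sp2,Lipo,-0.173,anchor
C(-CH2-),HBa,-2.0,anchor
C(≡CH),HBa,0.3,anchor
C(-CH3),HBd,-2.0,anchor
O(-OH),HBd,1.2,anchor
O_sp2,vdW,1.5,anchor
O(-OH),HBa,0.8,extension
O(-O-),HBa,0.5,extension
O_sp2,HBa,1.0,extension
O_minus,HBa,1.0,extension
N(amide),HBa,0.3,extension
N(generic),HBa,0.5,extension
F,HBa,0.1,extension
Cl,HBa,0.1,extension
N(generic),HBd,0.6,extension
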