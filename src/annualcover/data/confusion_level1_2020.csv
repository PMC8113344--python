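reference,RL,RP,CL,GL,BL,SL,FL,WL,OW,AC
RL,988,3,21,1,6,4,0,2,0,2
RP,1,988,26,1,4,1,8,0,0,1
CL,27,18,772,1,28,38,17,1,0,0
GL,1,15,57,990,15,8,64,0,0,0
BL,25,8,14,44,980,11,11,0,0,1
SL,0,4,23,13,17,986,44,1,0,3
FL,1,2,14,0,0,2,853,0,0,0
WL,3,2,119,0,0,0,53,1040,0,44
OW,0,3,0,0,0,0,0,1,1031,4
AC,4,7,4,0,0,0,0,5,19,995
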