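reference,R1,R2,RP,WC,OC,IC,GL,BL,SL,DBF,EBF,ENF,PL,MF,IW,OW,AC,BA
R1,804,137,3,0,10,0,2,6,1,0,0,0,0,0,0,0,3,0
R2,212,848,4,17,12,3,1,7,8,0,0,0,0,0,2,0,1,0
RP,0,1,932,5,27,1,3,5,0,2,0,0,5,0,0,0,0,0
WC,0,2,12,674,45,0,6,3,6,5,7,0,35,2,0,0,0,0
OC,0,2,27,26,801,2,1,5,11,3,2,0,15,0,1,0,0,0
IC,15,34,9,15,26,1044,0,26,84,6,0,0,0,0,0,0,0,0
GL,0,0,14,39,45,0,975,17,9,2,24,0,43,0,0,0,0,1
BL,16,14,11,8,12,0,40,960,10,6,1,0,5,0,0,1,4,0
SL,0,1,3,13,8,0,17,16,898,33,12,0,13,0,0,0,2,0
DBF,1,0,1,21,5,0,0,2,17,980,30,4,35,0,0,0,0,0
EBF,0,0,1,8,1,0,2,1,1,2,355,1,41,0,0,0,0,6
ENF,0,0,0,37,0,0,0,0,5,9,202,1045,19,0,0,0,0,0
PL,0,0,12,12,16,0,1,1,0,2,39,0,603,2,3,0,0,0
MF,0,6,2,7,2,0,0,1,0,0,2,0,17,1036,1,1,3,0
IW,0,3,7,160,35,0,0,0,0,0,0,0,100,2,1042,0,95,0
OW,1,0,2,0,0,0,0,0,0,0,0,0,0,1,0,1028,3,0
AC,1,2,10,0,3,0,0,0,0,0,0,0,0,6,1,20,939,0
BA,0,0,0,8,2,0,2,0,0,0,376,0,119,1,0,0,0,1043
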