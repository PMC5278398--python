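predicted,NHM,LC,RC,LW,RW,TK
NHM,3291,19,5,1,4,119
LC,2,3089,332,10,10,15
RC,1,320,3084,7,8,24
LW,1,4,8,3394,17,17
RW,8,4,2,19,3353,32
TK,147,14,19,19,58,3243
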