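prediction,STL,MER,HUD,DEL,RAPP,YOR,JAM,NEU,CF,SAN,STJ
STL,72,1,0,0,0,0,0,0,1,1,2
MER,3,257,1,0,1,0,0,0,0,0,7
HUD,2,3,46,0,0,0,0,0,2,0,4
DEL,0,0,0,26,0,0,0,0,0,0,0
RAPP,3,1,1,0,82,0,0,0,1,2,4
YOR,1,2,0,0,0,78,0,0,1,1,3
JAM,0,0,0,0,0,0,18,0,1,1,4
NEU,1,5,0,0,2,0,0,85,0,0,9
CF,2,3,1,0,0,0,0,2,109,0,6
SAN,1,2,0,0,0,0,0,2,4,71,3
STJ,0,4,0,0,1,0,0,0,1,1,193
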