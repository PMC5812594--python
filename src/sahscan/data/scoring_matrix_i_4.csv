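,A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,V,Y
A,0.3,1,0,1,0,0,1,0,0,0,0.3,1,0.3,0,-1.5,0.3,0.3,0,0,0
R,2,0,5,3.5,0,5,6.5,0,0,0,5,0,5,0,-1.5,2,2,0,0,0
N,4,9,0.3,9,0,0.3,9,0,0,0,0,9,0,0,-1.5,0,0,0,0,0
D,2,7,5,0,0,5,0,0,0,0,5,5.5,5,0,-1.5,2,2,0,0,0
C,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
Q,4,9,0.3,9,0,2,9,0,0,0,0,9,0,0,-1.5,0,0,0,0,0
E,2,10,5,0,0,5,0,0,0,0,5,8.5,5,0,-1.5,2,2,0,0,0
G,0,0,0,0,0,0,0,-1,0,0,0,0,0,0,-1.5,0,0,0,0,0
H,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
I,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
L,0.3,1,0,1,0,0,1,0,0,0,0,1,0,0,-1.5,0,0,0,0,0
K,2,0,5,3.5,0,5,6,0,0,0,5,0,5,0,-1.5,2,2,0,0,0
M,0.3,1,0,1,0,0,1,0,0,0,0,1,0,0,-1.5,0,0,0,0,0
F,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
P,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5,-1.5
S,1,0.5,0,0.5,0,0,0.5,0,0,0,0,0.5,0,0,-1.5,0,0,0,0,0
T,0.3,0.5,0,0.5,0,0,0.5,0,0,0,0,0.5,0,0,-1.5,0,0,0,0,0
W,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
V,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
Y,0,0,0,0,0,0,0,0,0,0,0,0,0,0,-1.5,0,0,0,0,0
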