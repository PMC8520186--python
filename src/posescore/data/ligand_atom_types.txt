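Br;1;1;0;0;0
C;4;0;4;0;0
C;4;1;1;0;0
C;4;1;2;0;0
C;4;1;3;0;0
C;4;2;0;0;0
C;4;2;0;0;1
C;4;2;1;0;0
C;4;2;1;0;1
C;4;2;1;1;1
C;4;2;2;0;0
C;4;2;2;0;1
C;4;3;0;0;0
C;4;3;0;0;1
C;4;3;0;1;1
C;4;3;1;0;0
C;4;3;1;0;1
C;4;4;0;0;0
C;4;4;0;0;1
Cl;1;1;0;0;0
F;1;1;0;0;0
I;1;1;0;0;0
N;2;1;0;0;0
N;3;1;0;0;0
N;3;1;1;0;0
N;3;1;2;0;0
N;3;2;0;0;0
N;3;2;0;1;1
N;3;2;1;0;0
N;3;2;1;0;1
N;3;2;1;1;1
N;3;3;0;0;0
N;3;3;0;0;1
N;3;3;0;1;1
N;4;1;2;0;0
N;4;1;3;0;0
N;4;2;0;0;0
N;4;2;1;0;0
N;4;2;1;1;1
N;4;2;2;0;0
N;4;2;2;0;1
N;4;3;0;0;0
N;4;3;0;0;1
N;4;3;0;1;1
N;4;3;1;0;1
N;4;4;0;0;0
N;4;4;0;0;1
O;1;1;0;0;0
O;2;1;0;0;0
O;2;1;1;0;0
O;2;2;0;0;0
O;2;2;0;0;1
O;2;2;0;1;1
P;3;1;2;0;0
P;3;2;1;0;1
P;3;3;0;0;0
P;3;3;0;0;1
P;4;4;0;0;0
P;5;4;0;0;0
P;5;4;0;0;1
S;1;1;0;0;0
S;2;1;0;0;0
S;2;1;1;0;0
S;2;2;0;0;0
S;2;2;0;0;1
S;2;2;0;1;1
S;3;3;0;0;0
S;4;3;0;0;0
S;4;3;0;0;1
S;6;4;0;0;0
S;6;4;0;0;1
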