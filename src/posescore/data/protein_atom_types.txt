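C;4;1;3;0;0
C;4;2;1;1;1
C;4;2;2;0;0
C;4;2;2;0;1
C;4;3;0;0;0
C;4;3;0;1;1
C;4;3;1;0;0
C;4;3;1;0;1
N;3;1;1;0;0
N;3;1;2;0;0
N;3;2;0;1;1
N;3;2;1;0;0
N;3;2;1;1;1
N;3;3;0;0;1
N;4;1;2;0;0
N;4;1;3;0;0
N;4;2;1;1;1
O;1;1;0;0;0
O;2;1;0;0;0
O;2;1;1;0;0
S;2;1;1;0;0
S;2;2;0;0;0
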