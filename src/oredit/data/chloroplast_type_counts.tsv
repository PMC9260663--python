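conversion	count
G>A	150
C>T	137
T>C	38
A>G	20
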