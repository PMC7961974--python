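SRC	A	+1
SRC	B	+1
A	OUT1	+1
B	OUT2	-1
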