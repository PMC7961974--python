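SRC	ACT	+1
SRC	INH	+1
ACT	OUT	+1
INH	OUT	-1
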