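Calm1	interacts	Kras
Calm1	interacts	Plcb4
Calm2	interacts	Kras
Calm2	interacts	Plcb4
Calm3	interacts	Kras
Calm3	interacts	Plcb4
Kras	interacts	Nr3c2
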