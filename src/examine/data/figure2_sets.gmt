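glioma	Glioma	Calm1	Calm2	Calm3	Kras
ltp	Long-term potentiation	Calm1	Calm2	Calm3	Kras	Plcb4
gnrh	GnRH signaling pathway	Calm1	Calm2	Calm3	Kras	Plcb4
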