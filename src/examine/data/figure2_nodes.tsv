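id	label	score	url
Calm1	Calm1	-0.8	
Calm2	Calm2	-1.2	
Calm3	Calm3	-0.5	
Kras	Kras	1.4	
Nr3c2	Nr3c2	-2.1	
Plcb4	Plcb4	1.9	
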