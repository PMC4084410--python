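id	category	p_value	weight
glioma	pathway	0.0001	1.0
ltp	pathway	0.0002	1.0
gnrh	pathway	0.0003	1.0
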