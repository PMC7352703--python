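het_class	count
heteroref	2296
heteroalt	1210
true	224
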