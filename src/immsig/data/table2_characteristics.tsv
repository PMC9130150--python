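variable	level	ais_low	ais_high
er_pr	negative	285	313
er_pr	positive	362	308
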