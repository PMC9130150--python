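arm	pcr_low_pct	pcr_low_count	pcr_high_pct	pcr_high_count
lapatinib	15.2	7	23.1	9
trastuzumab	9.8	4	41.7	15
combination	51.1	24	45.7	16
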