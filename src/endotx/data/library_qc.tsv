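statistic	CTR1	CTR2	CTR3	LPS1	LPS2	LPS3
raw_reads	107429702	89680918	84472314	97318676	90921644	95504908
trimmed_reads	99350630	82942056	78186984	89746640	83948534	87774992
mapped_reads	97654932	81309628	76784982	88226984	82560754	85830024
uniquely_mapped	89527396	60499072	58793660	80185286	70781032	73217060
multi_mapped	8066184	20785528	17964626	7990104	11741434	12567688
too_many_loci	61352	25028	26696	51594	38288	45276
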