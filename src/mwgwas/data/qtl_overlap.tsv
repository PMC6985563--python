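quantity	count
significant_snp_weighted	36
significant_snp_in_feed_efficiency_qtl	29
significant_snp_in_feed_intake_qtl	9
significant_snp_unweighted	2
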