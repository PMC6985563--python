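tissue	total_reads	n_libraries	mean_mapping_pct
hypothalamus	2014157388	30	96.91
duodenum	1653423084	30	98.25
jejunum	1809768258	30	99.59
ileum	1942804030	30	99.47
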