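tissue	n_expressed
hypothalamus	14205
duodenum	12824
jejunum	12734
ileum	13640
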