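b_allele	lineage
B*08:01	8
B*40:01	60
B*40:06	60
B*51:01	51
B*58:01	58
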