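C	B	count	freq
C*07:02	B*08:01	16	0.094
C*15:02	B*40:06	12	0.071
C*06:02	B*50:01	10	0.059
C*03:02	B*58:01	8	0.047
C*04:01	B*35:03	8	0.047
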