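C	B	DRB1	DQA1	DQB1	count	freq
C*07:02	B*08:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	16	0.094
C*15:02	B*40:06	DRB1*16:02	DQA1*01:02	DQB1*05:02	6	0.035
C*16:02	B*51:01	DRB1*16:01	DQA1*01:02	DQB1*05:02	5	0.029
C*03:02	B*58:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	4	0.024
C*03:02	B*58:01	DRB1*16:01	DQA1*01:02	DQB1*05:02	4	0.024
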