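DRB1	DQA1	DQB1	count	freq
DRB1*03:01	DQA1*05:01	DQB1*02:01	43	0.253
DRB1*16:01	DQA1*01:02	DQB1*05:02	15	0.088
DRB1*16:02	DQA1*01:02	DQB1*05:02	14	0.082
DRB1*11:02	DQA1*05:05	DQB1*03:01	7	0.041
DRB1*04:05	DQA1*03:03	DQB1*03:02	6	0.035
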