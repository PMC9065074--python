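family	label	A	C	B	DRB1	DQA1	DQB1	DPA1	DPB1	ceh	mpa	dup
HF39	b	A*02:01:01:01	C*16:02:01:01	B*51:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*02:01:02:05	51.2		0
HF22	a	A*02:01:01:01	C*16:02:01:01	B*51:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*02:01:02:05	51.2		0
HF8	a	A*32:01:01:01	C*16:02:01:01	B*51:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*02:01:02:01	51.2		0
HF8	f	A*32:01:01:01	C*16:02:01:01	B*51:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*02:01:02:01	51.2		0
HF8	j	A*32:01:01:01	C*16:02:01:01	B*51:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:05	DPB1*02:01:02:01	51.2		0
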