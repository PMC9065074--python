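family	label	A	C	B	DRB1	DQA1	DQB1	DPA1	DPB1	ceh	mpa	dup
HF26	c	A*02:01:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01	58.1	EA	0
HF10	d	A*23:01:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*02:01:01:03	DPB1*17:01:01:01	58.1	EA	0
HF17	b	A*33:03:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:02	DPB1*04:01:01:04	58.1	EA	0
HF7	a	A*33:03:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:02	DPB1*04:01:01:01	58.1	EA	0
DF14	d	A*33:03:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*16:01:01	DQA1*01:02:02	DQB1*05:02:01	DPA1*02:02:02	DPB1*13:01:01	58.2		0
HF39	d	A*33:03:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:04	DPB1*04:01:01:04	58.2		0
HF1	a	A*33:03:01:01	C*03:02:02:01	B*58:01:01:01	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01	58.2		0
DF14	d	A*33:03:01	C*03:02:02:01	B*58:01:01:01	DRB1*16:01:01	DQA1*01:02:02	DQB1*05:02:01	DPA1*02:02:02	DPB1*13:01:01	58.2		1
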