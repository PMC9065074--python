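family	label	A	C	B	DRB1	DQA1	DQB1	DPA1	DPB1	ceh	mpa	dup
HF6	a	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:04	DPB1*04:01:01:04			0
HF38	d	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*10:01:01:03	DQA1*01:05:01:01	DQB1*05:01:01:05	DPA1*01:03:01:01	DPB1*02:01:02:28			0
HF16	b	A*11:01:01:01	C*15:02:01:01	B*40:06:04:01	DRB1*14:04:01:02	DQA1*01:04:01:02	DQB1*05:03:01:01	DPA1*01:03:01:01	DPB1*02:01:02:01			0
HF30	b	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:01:01	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01			0
HF36	b	A*01:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02:01	DQB1*05:02:01	DPA1*01:03:01:02	DPB1*18:01:01:01	60.4		0
DF2	d	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02	DQB1*05:02:01	DPA1*01:03:01:04	DPB1*04:01	60.4		0
HF24	a	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*02:01:02:01	60.4		0
HF8	i	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:01	DPB1*04:02:01:02	60.4		0
HF29	b	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*01:03:01:05	DPB1*02:01:02:03	60.4		0
HF25	d	A*11:01:01:01	C*15:02:01:01	B*40:06:01:02	DRB1*16:02:01:02	DQA1*01:02:02:01	DQB1*05:02:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01	60.4		0
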