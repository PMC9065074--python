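family	label	A	C	B	DRB1	DQA1	DQB1	DPA1	DPB1	ceh	mpa	dup
DF24	a	A*26:01:01:01	C*07:02:01:01	B*08:01:01	DRB1*03:01:01	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*02:01:01	DPB1*04:01:01	8.2	SA	0
DF22	b	A*26:01:01:01	C*07:02:01:01	B*08:01:01	DRB1*03:01:01	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*02:01:01	DPB1*17:01	8.2	SA	0
DF13	a	A*26:01:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:01	DPB1*02:01:02:01	8.2	SA	0
HF20	b	A*26:01:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01	8.2	SA	0
DF31	a	A*26:01:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:03	DPB1*03:01:01:01	8.2	SA	0
DF24	d	A*68:01:01:02	C*07:02:01:01	B*08:01:01	DRB1*03:01:01	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:04	DPB1*04:01:01:01	8.2	SA	0
HF19	a	A*68:01:01:02	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:01	DPB1*02:01:02:05	8.2	SA	0
HF7	b	A*68:01:01:02	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:04	DPB1*04:01:01:06	8.2	SA	0
HF19	a	A*68:01:01:02	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:01	DPB1*02:01:02:05	8.2	SA	1
DF23	d	A*68:02:01:01	C*07:02:01:01	B*08:01:01	DRB1*03:01:01	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:05	DPB1*04:02:01:02	8.2	SA	0
HF9	a	A*24:02:01:04	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:05	DPB1*04:02:01:02	8.2	SA	0
HF9	b	A*24:02:01:04	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*01:03:01:05	DPB1*04:02:01:02	8.2	SA	0
HF9	c	A*24:02:01:05	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*02:07:01:01	DPB1*04:01:01:01	8.2	SA	0
HF28	c	A*03:02:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:03	DQB1*02:01:01:01	DPA1*01:03:01:03	DPB1*03:01:01:01	8.2	SA	0
HF7	d	A*02:01:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01	DPA1*02:01:01:06	DPB1*107:01	8.2	SA	0
HF29	a	A*11:01:01:01	C*07:02:01:01	B*08:01:01:01	DRB1*03:01:01:03	DQA1*05:01:01:03	DQB1*02:01:01:02	DPA1*01:03:01:01	DPB1*04:02:01:01	8.2	SA	0
HF11	d	A*29:02:01:01	C*07:01:01:01	B*08:01:01:01	DRB1*03:01:01:01	DQA1*05:01:01:02	DQB1*02:01:01:01	DPA1*02:01:01:02	DPB1*14:01:01:01	8.1	C	0
HF18	b	A*30:02:01:03	C*07:01:01:01	B*08:01:01:01	DRB1*03:01:01:02	DQA1*01:03:01:01	DQB1*06:01:01:01	DPA1*01:03:01:02	DPB1*04:01:01:04			0
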