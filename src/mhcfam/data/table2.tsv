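locus	allele	count	freq
DRB1	DRB1*03:01	49	0.29
DRB1	DRB1*16:02	16	0.09
DRB1	DRB1*16:01	15	0.09
DRB1	DRB1*11:01	12	0.07
DRB1	DRB1*04:05	9	0.05
DRB1	DRB1*07:01	9	0.05
DRB1	DRB1*01:01	6	0.04
DRB1	DRB1*04:02	6	0.04
DRB1	DRB1*01:02	6	0.03
DRB1	DRB1*11:04	5	0.03
DRB1	DRB1*15:01	5	0.03
DRB1	DRB1*15:02	4	0.02
DRB1	DRB1*15:03	4	0.02
DRB1	DRB1*10:01	3	0.02
DRB1	DRB1*03:02	2	0.01
DRB1	DRB1*04:03	2	0.01
DRB1	DRB1*04:06	2	0.01
DRB1	DRB1*09:01	2	0.01
DRB1	DRB1*13:01	2	0.01
DRB1	DRB1*03:07	1	0.01
DRB1	DRB1*04:01	1	0.01
DRB1	DRB1*04:04	1	0.01
DRB1	DRB1*08:04	1	0.01
DRB1	DRB1*11:02	1	0.01
DRB1	DRB1*13:02	1	0.01
DRB1	DRB1*13:03	1	0.01
DRB1	DRB1*14:04	1	0.01
DRB1	DRB1*14:15	1	0.01
DRB1	DRB1*14:21	1	0.01
DRB1	DRB1*15:06	1	0.01
DQA1	DQA1*05:01	48	0.28
DQA1	DQA1*01:02	42	0.25
DQA1	DQA1*05:05	16	0.09
DQA1	DQA1*03:03	12	0.07
DQA1	DQA1*01:01	11	0.07
DQA1	DQA1*03:01	11	0.07
DQA1	DQA1*01:03	9	0.05
DQA1	DQA1*02:01	7	0.04
DQA1	DQA1*01:05	4	0.02
DQA1	DQA1*01:04	3	0.02
DQA1	DQA1*04:01	3	0.02
DQA1	DQA1*03:02	2	0.01
DQA1	DQA1*05:09	1	0.01
DQB1	DQB1*02:01	49	0.29
DQB1	DQB1*05:02	35	0.21
DQB1	DQB1*03:02	18	0.11
DQB1	DQB1*05:01	14	0.08
DQB1	DQB1*03:01	13	0.08
DQB1	DQB1*02:02	10	0.06
DQB1	DQB1*06:01	8	0.05
DQB1	DQB1*04:02	6	0.04
DQB1	DQB1*06:02	6	0.04
DQB1	DQB1*05:03	3	0.02
DQB1	DQB1*03:19	1	0.01
DQB1	DQB1*03:27	1	0.01
DQB1	DQB1*03:35	1	0.01
DQB1	DQB1*06:03	1	0.01
DQB1	DQB1*06:04	1	0.01
DPA1	DPA1*01:03	114	0.67
DPA1	DPA1*02:01	42	0.25
DPA1	DPA1*02:02	6	0.04
DPA1	DPA1*02:07	3	0.02
DPA1	DPA1*03:01	2	0.01
DPA1	DPA1*01:04	1	0.01
DPA1	DPA1*01:14	1	0.01
DPA1	DPA1*02:09	1	0.01
DPB1	DPB1*04:01	52	0.31
DPB1	DPB1*02:01	34	0.20
DPB1	DPB1*14:01	17	0.10
DPB1	DPB1*04:02	14	0.08
DPB1	DPB1*01:01	7	0.04
DPB1	DPB1*03:01	7	0.04
DPB1	DPB1*13:01	6	0.04
DPB1	DPB1*17:01	6	0.04
DPB1	DPB1*104:01	6	0.04
DPB1	DPB1*10:01	4	0.02
DPB1	DPB1*18:01	4	0.02
DPB1	DPB1*09:01	3	0.02
DPB1	DPB1*105:01	2	0.01
DPB1	DPB1*107:01	2	0.01
DPB1	DPB1*15:01	1	0.01
DPB1	DPB1*26:01	1	0.01
DPB1	DPB1*39:01	1	0.01
DPB1	DPB1*45:01	1	0.01
DPB1	DPB1*91:01	1	0.01
DPB1	DPB1*124:01	1	0.01
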