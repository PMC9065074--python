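locus	allele	count	freq
A	A*02:01	25	0.15
A	A*11:01	18	0.11
A	A*24:02	14	0.08
A	A*32:01	13	0.08
A	A*03:01	12	0.07
A	A*68:01	12	0.07
A	A*01:01	11	0.06
A	A*30:02	10	0.06
A	A*26:01	9	0.05
A	A*30:01	7	0.04
A	A*33:03	7	0.04
A	A*23:01	6	0.04
A	A*03:02	4	0.02
A	A*29:02	3	0.02
A	A*31:01	2	0.01
A	A*68:02	2	0.01
A	A*01:03	1	0.01
A	A*02:02	1	0.01
A	A*02:03	1	0.01
A	A*02:09	1	0.01
A	A*02:11	1	0.01
A	A*26:17	1	0.01
A	A*29:01	1	0.01
A	A*29:10	1	0.01
A	A*30:04	1	0.01
A	A*33:01	1	0.01
A	A*34:02	1	0.01
A	A*36:01	1	0.01
A	A*66:02	1	0.01
A	A*69:01	1	0.01
A	A*74:01	1	0.01
C	C*04:01	32	0.19
C	C*07:02	21	0.12
C	C*06:02	20	0.12
C	C*15:02	18	0.11
C	C*07:01	10	0.06
C	C*16:02	10	0.06
C	C*03:02	9	0.05
C	C*12:03	6	0.04
C	C*08:02	5	0.03
C	C*12:02	5	0.03
C	C*17:01	5	0.03
C	C*15:05	4	0.02
C	C*01:02	2	0.01
C	C*02:02	2	0.01
C	C*03:04	2	0.01
C	C*07:04	2	0.01
C	C*14:02	2	0.01
C	C*15:04	2	0.01
C	C*15:13	2	0.01
C	C*16:01	2	0.01
C	C*02:10	1	0.01
C	C*02:16	1	0.01
C	C*03:03	1	0.01
C	C*04:03	1	0.01
C	C*07:18	1	0.01
C	C*08:01	1	0.01
C	C*12:19	1	0.01
C	C*16:04	1	0.01
C	C*18:01	1	0.01
B	B*51:01	20	0.12
B	B*08:01	18	0.11
B	B*40:06	13	0.08
B	B*50:01	11	0.06
B	B*18:01	10	0.06
B	B*58:01	9	0.05
B	B*35:01	8	0.05
B	B*35:03	8	0.05
B	B*53:01	6	0.04
B	B*35:08	5	0.03
B	B*52:01	5	0.03
B	B*07:02	4	0.02
B	B*14:02	4	0.02
B	B*41:01	4	0.02
B	B*42:01	4	0.02
B	B*57:01	4	0.02
B	B*38:01	3	0.02
B	B*45:01	3	0.02
B	B*07:05	2	0.01
B	B*13:01	2	0.01
B	B*15:10	2	0.01
B	B*27:03	2	0.01
B	B*35:02	2	0.01
B	B*39:01	2	0.01
B	B*44:02	2	0.01
B	B*58:02	2	0.01
B	B*13:02	1	0.01
B	B*14:01	1	0.01
B	B*15:02	1	0.01
B	B*15:03	1	0.01
B	B*15:17	1	0.01
B	B*15:22	1	0.01
B	B*15:67	1	0.01
B	B*37:01	1	0.01
B	B*40:16	1	0.01
B	B*44:03	1	0.01
B	B*47:03	1	0.01
B	B*51:08	1	0.01
B	B*55:01	1	0.01
B	B*73:01	1	0.01
B	B*81:01	1	0.01
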