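DPA1	DPB1	count	freq
DPA1*01:03	DPB1*04:01	47	0.276
DPA1*01:03	DPB1*02:01	32	0.188
DPA1*02:01	DPB1*14:01	15	0.088
DPA1*01:03	DPB1*04:02	14	0.082
DPA1*01:03	DPB1*104:01	6	0.035
DPA1*02:01	DPB1*17:01	6	0.035
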