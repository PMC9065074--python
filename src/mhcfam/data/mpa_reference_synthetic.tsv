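region	C	B	DRB1	DQA1	DQB1	freq
South Asian	C*07:02	B*08:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	0.12
Caucasian	C*07:01	B*08:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	0.12
East Asian	C*03:02	B*58:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	0.12
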