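name	C	B	DRB1	DQA1	DQB1	ancestry
8.1	C*07:01	B*08:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	Caucasian
8.2	C*07:02	B*08:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	South Asian
58.1	C*03:02	B*58:01	DRB1*03:01	DQA1*05:01	DQB1*02:01	East Asian
60.1	C*03:04	B*40:01	DRB1*04:04	DQA1*03:01	DQB1*03:02	
60.2	C*03:04	B*40:01	DRB1*08:01	DQA1*04:01	DQB1*04:02	
60.3	C*03:04	B*40:01	DRB1*13:02	DQA1*01:02	DQB1*06:04	
51.1						
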