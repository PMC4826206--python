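mirna	target	evidence
miR-132	RB1	strong
miR-221	RB1	strong
miR-335	RB1	strong
miR-192	RB1	strong
miR-106a	RB1	strong
miR-106b	RB1	strong
miR-519a	RB1	strong
miR-215	RB1	strong
miR-212	RB1	strong
miR-26b	RB1	strong
miR-26a	RB1	strong
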