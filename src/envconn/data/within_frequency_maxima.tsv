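band_seed	band_target	x	y	z
theta	theta	-54	-32	-1
theta	theta	-52	-46	-12
alpha	alpha	-47	-58	34
alpha	alpha	-32	-51	-13
alpha	alpha	-65	-27	1
beta	beta	-49	-26	17
beta	beta	-45	13	25
low_gamma	low_gamma	-47	12	22
low_gamma	low_gamma	-41	-7	-4
low_gamma	low_gamma	-45	7	36
beta	beta	6	26	17
low_gamma	low_gamma	45	-8	6
alpha	alpha	-6	-32	37
alpha	alpha	6	-37	40
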