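band_seed	band_target	x	y	z
theta	low_gamma	-22	-64	7
alpha	theta	-43	-64	10
alpha	low_gamma	-7	-58	15
beta	theta	-46	-54	18
beta	theta	-50	-47	-12
low_gamma	beta	-21	-38	-4
theta	low_gamma	46	-35	63
theta	low_gamma	12	-62	60
alpha	theta	-2	-69	48
alpha	theta	21	-76	31
alpha	beta	11	-45	29
alpha	low_gamma	7	-62	49
beta	low_gamma	5	-30	41
theta	low_gamma	-19	-53	61
alpha	theta	-40	-60	44
alpha	theta	-33	-64	47
alpha	low_gamma	-15	-58	55
beta	theta	-28	-50	44
theta	alpha	-41	15	17
theta	alpha	-43	13	3
theta	alpha	-41	-3	-4
theta	alpha	-55	-8	7
theta	beta	-35	10	10
beta	alpha	-44	6	15
low_gamma	alpha	-49	-1	38
low_gamma	beta	-55	14	18
theta	beta	-54	-30	12
alpha	theta	-64	-27	18
alpha	theta	-65	-28	15
alpha	theta	-69	-35	5
alpha	beta	-67	-32	11
alpha	beta	-68	-33	9
beta	theta	-58	-23	18
theta	alpha	-52	-41	28
theta	beta	-55	-50	28
theta	low_gamma	-50	-59	35
theta	low_gamma	-61	-35	40
theta	low_gamma	-60	-34	42
theta	low_gamma	-57	-19	51
theta	low_gamma	-55	-41	25
alpha	theta	-51	-61	20
alpha	low_gamma	-51	-28	44
beta	alpha	-46	-50	26
beta	low_gamma	-50	-37	31
theta	alpha	47	-38	16
alpha	theta	32	-53	-19
alpha	theta	40	-57	26
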