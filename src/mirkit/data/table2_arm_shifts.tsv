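mirna	annotated_arm	detected_arm	ratio_sf	ratio_bf
miR-133	5p	3p	0.01	0.01
miR-1891	5p	3p	0.37	0.27
miR-278	3p	5p	1.33	1.34
miR-281	3p	5p	24.81	22.59
miR-965	3p	5p	23.56	9.56
miR-929	3p	5p	27.92	14.67
miR-1889	3p	5p~3p	0.93	0.72
miR-305	5p	5p~3p	1.02	0.85
miR-219	5p	5p	1.91	0.91
miR-3840	novel	3p	0.24	1
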