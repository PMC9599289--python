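symbol	exosomal	dir_pancreatitis_vs_healthy	dir_pdac_vs_pancreatitis	mature_arms
MIR27A	1	unknown	up	miR-27a-5p,miR-27a-3p
MIR31	1	down	up	miR-31-5p,miR-31-3p
MIR93	1	unknown	up	miR-93-5p,miR-93-3p
MIR96	1	down	unknown	miR-96-5p,miR-96-3p
MIR122	1	unknown	unknown	miR-122-5p,miR-122-3p
MIR130B	1	down	up	miR-130b-5p,miR-130b-3p
MIR133A1	1	unknown	unknown	miR-133a-5p,miR-133a-3p
MIR203A	1	unknown	unknown	miR-203a-5p,miR-203a-3p
MIR210	1	down	unknown	miR-210-5p,miR-210-3p
MIR330	1	unknown	up	miR-330-5p,miR-330-3p
MIR339	1	down	unknown	miR-339-5p,miR-339-3p
MIR425	1	unknown	unknown	miR-425-5p,miR-425-3p
MIR429	1	down	unknown	miR-429
MIR522	1	unknown	unknown	miR-522-5p,miR-522-3p
MIR590	1	down	unknown	miR-590-5p,miR-590-3p
MIR664A	1	unknown	unknown	miR-664a-5p,miR-664a-3p
MIR1208	1	down	unknown	miR-1208
MIR3620	1	unknown	unknown	miR-3620-5p,miR-3620-3p
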