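family,cell_line,p_value,preferred_arm,one_arm_undetected
miR-31,PANC1,,none,0
miR-31,BXPC3,,none,0
miR-31,CAPAN2,,none,0
miR-93,PANC1,0.01,5p,0
miR-93,BXPC3,,none,0
miR-93,CAPAN2,0.01,5p,0
miR-133a,PANC1,,none,1
miR-133a,BXPC3,,none,1
miR-133a,CAPAN2,,none,1
miR-210,PANC1,0.01,3p,1
miR-210,BXPC3,,none,1
miR-210,CAPAN2,,none,1
miR-330,PANC1,,none,0
miR-330,BXPC3,,none,0
miR-330,CAPAN2,,none,0
miR-339,PANC1,,none,0
miR-339,BXPC3,,none,0
miR-339,CAPAN2,0.05,5p,0
miR-425,PANC1,0.05,5p,0
miR-425,BXPC3,,none,0
miR-425,CAPAN2,0.01,5p,0
miR-3620,PANC1,,none,0
miR-3620,BXPC3,,none,0
miR-3620,CAPAN2,,none,0
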