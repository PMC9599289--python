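cell_line,mir,p_value,p_is_bound,log2_fc
PANC1,miR-31-5p,0.05,1,
PANC1,miR-31-3p,0.01,1,
PANC1,miR-93-5p,0.0691,0,
PANC1,miR-93-3p,0.7759,0,
PANC1,miR-133a-3p,0.3000,0,
PANC1,miR-210-3p,0.05,1,
PANC1,miR-339-5p,0.1412,0,
PANC1,miR-339-3p,0.1416,0,
PANC1,miR-425-5p,0.001,1,
PANC1,miR-425-3p,0.380,0,
BXPC3,miR-31-5p,0.05,1,
BXPC3,miR-31-3p,0.05,1,
BXPC3,miR-93-5p,0.0770,0,
BXPC3,miR-210-3p,0.05,1,
BXPC3,miR-339-5p,0.001,1,
BXPC3,miR-425-5p,0.05,1,
BXPC3,miR-425-3p,0.05,1,
BXPC3,miR-429,0.01,1,7.67
CAPAN2,miR-31-5p,0.001,1,
CAPAN2,miR-31-3p,0.001,1,
CAPAN2,miR-93-5p,0.2412,0,
CAPAN2,miR-210-3p,0.9928,0,
CAPAN2,miR-339-5p,0.1499,0,
CAPAN2,miR-339-3p,0.9769,0,
CAPAN2,miR-425-5p,0.05,1,
CAPAN2,miR-425-3p,0.381,0,
CAPAN2,miR-429,0.01,1,7.28
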