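label,region,c10_pa,k1_pa,k2,alpha_deg,kappa,thickness_mm
tl_wall,both,78219,201440,1.52,87.1,0.2,1.76
mid_fl_wall,mid,53456,952380,4.94,7.5,0.3,1.3
distal_fl_wall,distal,72996,20894,9.01,66.5,0,1.24
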