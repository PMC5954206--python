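label,region,pig,c10_pa,k1_pa,k2,alpha_deg,kappa,thickness_mm
mid_1,mid,1,92963,230290,13.9,87.1,0.33,0.58
mid_2,mid,2,73144,235075,7.86,68.7,0.3,0.59
mid_3,mid,3,64042,212120,4.99,23.5,0.32,0.54
mid_4,mid,4,52072,125430,5.87,53.9,0.26,0.70
mid_5,mid,5,45588,149880,1.42,55.6,0.21,0.47
distal_1,distal,1,103140,61969,4.1,62.4,0.1,0.4
distal_2,distal,2,171740,661830,8.05,86.5,0.3,0.34
distal_3,distal,3,78686,239090,3.18,89.9,0.3,0.43
distal_4,distal,4,63554,77013,4.76,83.4,0.11,0.29
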