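label,type_A_pct,type_B_pct
Physical dimensions,<0.01,0.09
Electrical calibrations,0.20,0.06
Specific heat capacity,0.08,0.26
k_imp * k_gap,0.01,0.14
s_wg * k_fl,0.07,0.71
k_z_cal,,0.10
Positioning on beam axis and reference depth,0.06,0.13
PCB,,0.25
Calorimeter measurements and analysis,0.04,0.15
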