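time_h,target_ppm,sampling_vol_m3,c_in_ugm3,c_out_ugm3,recovery_pct
24,0.2,0.012,245,234,96
48,0.2,0.012,244,236,97
72,0.2,0.012,242,237,98
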