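case,target_ppm,temp_c,rh_pct,c_in_te_ugm3,er_mg_m2_h,c_steady_ugm3,risk_male_e6,risk_female_e6,risk_reduction_male_e6,risk_reduction_female_e6
LP-1,0.2,25,50,251.6,0.017,22.7,54.8,46.3,553,468
LP-1,0.2,25,75,242.7,0.018,24.0,58.0,49.0,528,447
LP-1,0.2,30,50,242.5,0.015,20.0,48.3,40.8,538,454
LP-1,0.2,30,75,243.9,0.04,53.3,128.9,108.9,460,389
MCP-2,0.1,25,50,129.5,0.018,24.0,58.0,49.0,255,215
MCP-2,0.2,25,50,238.0,0.004,5.3,12.9,10.9,562,475
MCP-2,0.2,30,50,245.0,0.006,8.0,19.3,16.3,573,484
CS-3,0.1,25,50,134.8,0.021,28.0,67.7,57.2,258,218
CS-3,0.2,25,50,252.6,0.024,32.0,77.3,65.4,533,451
CS-3,0.2,30,50,239.4,0.027,36.0,87.0,73.5,491,415
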