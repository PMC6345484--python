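case,material,target_ppm,temp_c,rh_pct,c_in_ugm3,sd_in,c_out_ugm3,sd_out,sb_m,sb_v_eq,adsorption_rate_pct,er_mg_m2_h
LP-1,latex paint,0.2,25,50,252,10.8,151,23.7,124.9,0.83,40.1,0.017
LP-1,latex paint,0.2,25,75,243,9.3,156,13.2,107.8,0.69,35.9,0.018
LP-1,latex paint,0.2,30,50,243,8.0,207,21.6,44.6,0.22,14.9,0.015
LP-1,latex paint,0.2,30,75,244,5.9,209,4.0,42.9,0.21,14.2,0.04
MCP-2,micro-carbonized plywood,0.1,25,50,130,5.6,97,4.1,40.3,0.42,25.1,0.018
MCP-2,micro-carbonized plywood,0.2,25,50,238,8.6,118,6.5,148.6,1.26,50.5,0.004
MCP-2,micro-carbonized plywood,0.2,30,50,245,6.8,129,8.3,144.1,1.12,47.5,0.006
CS-3,Celite siding,0.1,25,50,135,3.1,72,1.3,77.9,1.08,46.7,0.021
CS-3,Celite siding,0.2,25,50,253,14.8,117,4.4,168.0,1.44,53.8,0.024
CS-3,Celite siding,0.2,30,50,239,5.6,119,6.8,148.9,1.25,50.2,0.027
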