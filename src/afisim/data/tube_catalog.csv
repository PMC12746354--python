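name,pvp_wt_percent,contrast_agent_vol_percent,eps_r,sigma_S_per_m,t1_3t_ms,t1_7t_ms,t2_3t_ms,t2_7t_ms,adc_um2_s
PVP1,5,0,76.4,0.57,2347,2442,1195,1028,1870
PVP2,10,0,73.6,0.61,2037,2106,1112,898,1610
PVP3,15,0,70.6,0.59,1731,1838,962,739,1380
PVP4,20,0,67.5,0.51,1501,1618,790,603,1200
PVP5,23,0,66.4,0.62,1292,1401,780,604,990
PVP6,38,0,57.8,0.60,751,808,475,327,530
PVP7,44,0,53.3,0.55,546,609,343,231,350
PVP8,50,0,50.1,0.56,410,486,250,179,240
W1,0,0.016,,,1301,1291,585,380,1930
W2,0,0.038,,,815,808,525,390,1980
W3,0,0.060,,,587,583,397,318,1950
W4,0,0.084,,,455,452,328,267,1910
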