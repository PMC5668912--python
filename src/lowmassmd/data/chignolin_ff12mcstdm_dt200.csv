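timestep_fs,aggregated_time_us,mean_pct,sd_pct,se_pct,tau_ns,lcl_ns,ucl_ns,events
2.00,0.400,1,3,1,,,,2
2.00,0.800,2,6,1,,,,4
2.00,1.200,5,10,2,,,,9
2.00,1.600,8,12,3,,,,10
2.00,2.000,13,16,4,128,71,231,11
2.00,2.400,16,19,4,122,71,209,13
2.00,2.800,17,20,4,132,76,227,13
2.00,3.200,18,20,4,132,78,222,14
2.00,3.600,19,19,4,114,71,184,17
2.00,4.000,20,18,4,105,67,164,19
2.00,4.400,22,17,4,106,67,165,19
2.00,4.800,24,16,4,107,68,167,19
2.00,5.200,26,16,4,108,69,169,19
2.00,5.600,27,17,4,109,69,171,19
2.00,6.000,28,17,4,110,70,172,19
2.00,8.000,31,17,4,114,73,179,19
2.00,10.000,34,17,4,120,77,188,19
2.00,12.000,34,15,3,125,80,196,19
2.00,14.000,34,14,3,130,83,204,19
2.00,16.000,35,15,3,136,87,212,19
2.00,18.000,35,14,3,141,90,221,19
2.00,20.000,35,13,3,147,94,230,19
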