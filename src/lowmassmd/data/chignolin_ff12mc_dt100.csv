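timestep_fs,aggregated_time_us,mean_pct,sd_pct,se_pct,tau_ns,lcl_ns,ucl_ns,events
1.00,0.632,3,7,2,,,,4
1.00,1.264,7,17,4,,,,7
1.00,1.896,14,22,5,87,53,145,15
1.00,2.528,18,25,5,92,56,150,16
1.00,3.160,22,26,6,82,53,129,19
1.00,3.792,26,26,6,79,51,123,20
1.00,4.424,30,26,6,79,51,123,20
1.00,5.056,31,25,6,79,51,123,20
1.00,5.688,33,24,5,79,51,123,20
1.00,6.320,33,23,5,79,51,123,20
1.00,6.952,34,22,5,79,51,123,20
1.00,7.584,35,21,5,79,51,123,20
1.00,8.216,35,21,5,79,51,123,20
1.00,8.848,35,20,5,79,51,123,20
1.00,9.480,36,20,4,79,51,123,20
1.00,12.640,36,14,3,79,51,123,20
1.00,15.800,38,13,3,79,51,123,20
1.00,18.960,36,12,3,79,51,123,20
1.00,22.120,35,13,3,79,51,123,20
1.00,25.280,35,12,3,79,51,123,20
1.00,28.440,35,12,3,79,51,123,20
1.00,31.600,35,12,3,79,51,123,20
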