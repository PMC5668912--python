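timestep_fs,aggregated_time_us,mean_pct,sd_pct,se_pct,tau_ns,lcl_ns,ucl_ns,events
3.16,0.632,3,8,2,,,,4
3.16,1.264,8,17,4,,,,10
3.16,1.896,16,23,5,95,55,163,13
3.16,2.528,21,22,5,74,47,118,18
3.16,3.160,24,21,5,73,47,114,19
3.16,3.792,28,21,5,74,48,117,19
3.16,4.424,31,20,4,72,47,112,20
3.16,5.056,34,20,4,72,47,112,20
3.16,5.688,36,20,4,72,47,112,20
3.16,6.320,38,19,4,72,47,112,20
3.16,6.952,38,18,4,72,47,112,20
3.16,7.584,37,17,4,72,47,112,20
3.16,8.216,37,17,4,72,47,112,20
3.16,8.848,37,17,4,72,47,112,20
3.16,9.480,37,17,4,72,47,112,20
3.16,12.640,39,15,3,72,47,112,20
3.16,15.800,39,15,3,72,47,112,20
3.16,18.960,38,13,3,72,47,112,20
3.16,22.120,37,12,3,72,47,112,20
3.16,25.280,37,11,2,72,47,112,20
3.16,28.440,37,9,2,72,47,112,20
3.16,31.600,37,7,2,72,47,112,20
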