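condition,temp_K,timestep_fs,aggregated_time_us,mean_pct,sd_pct,se_pct
FF14SBlm,277,1.00,3.16,0,1,0
FF14SBlm,277,1.00,6.32,0,1,0
FF14SBlm,277,1.00,9.48,4,10,2
FF14SBlm,277,1.00,12.64,6,15,3
FF14SBlm,277,1.00,15.80,9,19,4
FF14SBlm,277,1.00,18.96,12,22,5
FF14SBlm,277,1.00,22.12,14,24,5
FF14SBlm,277,1.00,25.28,15,26,6
FF14SBlm,277,1.00,28.44,16,27,6
FF14SBlm,277,1.00,31.60,17,28,6
FF14SB,277,3.16,3.16,0,0,0
FF14SB,277,3.16,6.32,4,11,3
FF14SB,277,3.16,9.48,6,17,4
FF14SB,277,3.16,12.64,9,21,5
FF14SB,277,3.16,15.80,12,24,5
FF14SB,277,3.16,18.96,15,24,5
FF14SB,277,3.16,22.12,18,25,6
FF14SB,277,3.16,25.28,21,26,6
FF14SB,277,3.16,28.44,23,28,6
FF14SB,277,3.16,31.60,26,29,6
FF14SB,277,2.00,2.00,0,0,0
FF14SB,277,2.00,4.00,0,0,0
FF14SB,277,2.00,6.00,0,1,0
FF14SB,277,2.00,8.00,1,4,1
FF14SB,277,2.00,10.00,3,8,2
FF14SB,277,2.00,12.00,4,11,3
FF14SB,277,2.00,14.00,5,14,3
FF14SB,277,2.00,16.00,6,15,3
FF14SB,277,2.00,18.00,8,17,4
FF14SB,277,2.00,20.00,9,19,4
FF12MCstdm,340,3.16,3.16,29,26,6
FF12MCstdm,340,3.16,6.32,36,16,4
FF12MCstdm,340,3.16,9.48,41,14,3
FF12MCstdm,340,3.16,12.64,41,13,3
FF12MCstdm,340,3.16,15.80,42,12,3
FF12MCstdm,340,3.16,18.96,42,10,2
FF12MCstdm,340,3.16,22.12,41,9,2
FF12MCstdm,340,3.16,25.28,41,9,2
FF12MCstdm,340,3.16,28.44,42,9,2
FF12MCstdm,340,3.16,31.60,41,9,2
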