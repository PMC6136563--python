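landmark,stress_period,stress_MPa,movement_period,movement_mm
C1M,T0,0.062,T0-1,1.153
C1D,T0,0.059,T0-1,1.003
C2D,T0,0.041,T0-1,0.221
C1M,T1,0.058,T1-2,1.221
C1D,T1,0.063,T1-2,1.378
C2D,T1,0.043,T1-2,0.194
C1M,T2,0.052,T2-3,0.827
C1D,T2,0.056,T2-3,0.723
C2D,T2,0.028,T2-3,0.859
C1M,T3,0.057,T3-4,0.464
C1D,T3,0.049,T3-4,0.321
C2D,T3,0.036,T3-4,0.367
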