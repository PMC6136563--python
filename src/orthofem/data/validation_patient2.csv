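landmark,stress_period,stress_MPa,movement_period,predicted_mm,clinical_mm,diff_mm,percent
C1M,T0,0.063,T0-1,1.378,1.296,0.082,5.95
C1D,T0,0.061,T0-1,1.153,1.211,0.058,5.03
C2D,T0,0.039,T0-1,0.241,0.223,0.018,7.61
C1M,T1,0.062,T1-2,1.263,1.258,0.005,0.36
C1D,T1,0.059,T1-2,0.952,1.037,0.085,8.96
C2D,T1,0.041,T1-2,0.206,0.219,0.013,6.39
C1M,T2,0.053,T2-3,0.490,0.487,0.003,0.61
C1D,T2,0.051,T2-3,0.383,0.395,0.012,3.01
C2D,T2,0.048,T2-3,0.268,0.272,0.004,1.49
C1M,T3,0.030,T3-4,0.694,0.674,0.020,2.92
C1D,T3,0.031,T3-4,0.620,0.630,0.010,1.57
C2D,T3,0.034,T3-4,0.434,0.451,0.017,3.97
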