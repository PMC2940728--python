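8
synthetic 8-atom compact/folded reference structure (Angstrom)
C 5.740 -0.977 -9.500
C -1.028 -2.702 2.170
C 0.877 -1.980 0.640
C 6.070 0.334 8.488
C -3.929 -1.674 3.299
C -0.751 -4.323 -6.164
C -1.637 2.217 -6.669
C -5.342 9.105 7.736
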