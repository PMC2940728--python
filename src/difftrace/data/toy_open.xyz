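8
synthetic 8-atom open/unfolded reference structure (Angstrom)
C 4.790 -0.386 -4.201
C 3.930 -2.129 5.858
C 4.094 1.944 1.806
C 8.374 1.776 6.526
C -4.821 -0.223 -1.692
C -7.400 -2.847 -4.935
C -6.783 -1.275 -6.980
C -2.183 3.140 3.618
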