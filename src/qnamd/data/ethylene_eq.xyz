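6
ethylene CASCI(4,3)/6-31G minimum
C       0.672112577648     0.000000000000     0.000000000000
C      -0.672112577648     0.000000000000     0.000000000000
H       1.237403574302     0.912902105279     0.000000000000
H       1.237403574302    -0.912902105279     0.000000000000
H      -1.237403574302     0.912902105279     0.000000000000
H      -1.237403574302    -0.912902105279     0.000000000000
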