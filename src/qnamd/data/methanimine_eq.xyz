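5
methanimine CASCI(4,3)/6-31G minimum
C       0.000000000000     0.000000000000     0.000000000000
N       1.286182572578     0.000000000000     0.000000000000
H      -0.606554729833     0.891301974114     0.000000000000
H      -0.516228691948    -0.939680170750     0.000000000000
H       1.709166909643     0.915269282914     0.000000000000
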