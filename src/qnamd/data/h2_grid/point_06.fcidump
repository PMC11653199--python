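&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.3110020112905851e-01    1    1    1    1
 1.9513072395287948e-01    2    1    2    1
 6.2565530244230605e-01    2    2    1    1
 6.5730843812177786e-01    2    2    2    2
-1.1239703538722428e+00    1    1    0    0
-5.8108779678440159e-01    2    2    0    0
 5.4347826086956530e-01    0    0    0    0
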