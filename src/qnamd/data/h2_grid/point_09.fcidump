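&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 5.9371126561468834e-01    1    1    1    1
 2.0952313775373538e-01    2    1    2    1
 5.9448949013200747e-01    2    2    1    1
 6.2328264432122471e-01    2    2    2    2
-1.0212950970376904e+00    1    1    0    0
-6.3333762535780569e-01    2    2    0    0
 4.4247787610619471e-01    0    0    0    0
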