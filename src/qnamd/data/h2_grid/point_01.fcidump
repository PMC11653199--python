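&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 7.0072594380403008e-01    1    1    1    1
 1.7389646546000601e-01    2    1    2    1
 6.8819497792474760e-01    2    2    1    1
 7.2385658063505298e-01    2    2    2    2
-1.3400494629664885e+00    1    1    0    0
-3.6885298503847719e-01    2    2    0    0
 8.7719298245614041e-01    0    0    0    0
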