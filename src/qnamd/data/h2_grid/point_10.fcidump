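&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 5.8257492079339535e-01    1    1    1    1
 2.1443015670822524e-01    2    1    2    1
 5.8519478032869243e-01    2    2    1    1
 6.1283938822037953e-01    2    2    2    2
-9.9097045688429330e-01    1    1    0    0
-6.4444239265760439e-01    2    2    0    0
 4.1666666666666669e-01    0    0    0    0
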