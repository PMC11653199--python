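&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.7257486256473986e-01    1    1    1    1
 1.8185213890829616e-01    2    1    2    1
 6.6172971079695930e-01    2    2    1    1
 6.9555312900506183e-01    2    2    2    2
-1.2464255392670232e+00    1    1    0    0
-4.8214592932624734e-01    2    2    0    0
 7.0422535211267612e-01    0    0    0    0
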