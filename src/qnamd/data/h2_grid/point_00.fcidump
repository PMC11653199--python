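&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 7.1443907903371584e-01    1    1    1    1
 1.7024144384084905e-01    2    1    2    1
 7.0185315606834764e-01    2    2    1    1
 7.3883669331375823e-01    2    2    2    2
-1.3902192705885092e+00    1    1    0    0
-2.9165330496719627e-01    2    2    0    0
 1.0000000000000000e+00    0    0    0    0
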