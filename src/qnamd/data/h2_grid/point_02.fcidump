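&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.8670685446583613e-01    1    1    1    1
 1.7777410037042857e-01    2    1    2    1
 6.7476586232136937e-01    2    2    1    1
 7.0940525023080792e-01    2    2    2    2
-1.2920627921283636e+00    1    1    0    0
-4.3165783953159603e-01    2    2    0    0
 7.8125000000000000e-01    0    0    0    0
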