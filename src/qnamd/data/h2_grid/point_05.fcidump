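&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.4462649698730567e-01    1    1    1    1
 1.9054740998326458e-01    2    1    2    1
 6.3714392580633850e-01    2    2    1    1
 6.6955220851872410e-01    2    2    2    2
-1.1624338200654076e+00    1    1    0    0
-5.5495625004726545e-01    2    2    0    0
 5.8823529411764708e-01    0    0    0    0
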