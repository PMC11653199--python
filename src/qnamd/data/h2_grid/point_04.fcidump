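&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.5849748791082319e-01    1    1    1    1
 1.8611495659203137e-01    2    1    2    1
 6.4917487872392221e-01    2    2    1    1
 6.8228474965862018e-01    2    2    2    2
-1.2032211617017630e+00    1    1    0    0
-5.2255201971080500e-01    2    2    0    0
 6.4102564102564097e-01    0    0    0    0
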