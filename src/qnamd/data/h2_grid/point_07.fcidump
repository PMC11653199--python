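&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.1804103701670343e-01    1    1    1    1
 1.9984087078381352e-01    2    1    2    1
 6.1471613672152725e-01    2    2    1    1
 6.4552206974703874e-01    2    2    2    2
-1.0877042459315038e+00    1    1    0    0
-6.0226677956457897e-01    2    2    0    0
 5.0505050505050508e-01    0    0    0    0
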