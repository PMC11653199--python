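&FCI NORB=2,NELEC=2,MS2=0,
  ORBSYM=1,1,
  ISYM=1,
&END
 6.0555158045141788e-01    1    1    1    1
 2.0464900881820827e-01    2    1    2    1
 6.0432814960379233e-01    2    2    1    1
 6.3417984836331531e-01    2    2    2    2
-1.0535129426268934e+00    1    1    0    0
-6.1945236037843154e-01    2    2    0    0
 4.7169811320754712e-01    0    0    0    0
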