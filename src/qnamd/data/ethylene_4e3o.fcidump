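&FCI NORB=3,NELEC=4,MS2=0,
  ORBSYM=1,1,1,
  ISYM=1,
&END
 3.8519241835975387e-01    1    1    1    1
 8.1595595805278396e-03    2    1    2    1
 3.5564742033685715e-01    2    2    1    1
 4.4389359303584203e-01    2    2    2    2
 1.0958588835473373e-02    3    1    3    1
 1.1168867819719187e-01    3    2    3    2
 3.3971176845093409e-01    3    3    1    1
 4.0040340757381593e-01    3    3    2    2
 3.7988652048101490e-01    3    3    3    3
-1.5918629118968239e+00    1    1    0    0
-1.5163894510299258e+00    2    2    0    0
-1.1855764425353914e+00    3    3    0    0
-7.4022687186488525e+01    0    0    0    0
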