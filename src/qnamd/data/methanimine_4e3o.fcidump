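&FCI NORB=3,NELEC=4,MS2=0,
  ORBSYM=1,1,1,
  ISYM=1,
&END
 4.8677320757825487e-01    1    1    1    1
 1.9288758594030703e-02    2    1    2    1
 4.3605321815777942e-01    2    2    1    1
 5.3705657099456805e-01    2    2    2    2
-4.0646070435163259e-02    3    1    1    1
-9.3866671882937222e-02    3    1    2    2
 1.2956688947693989e-01    3    1    3    1
-1.5823048138555125e-02    3    2    2    1
 1.9883110656762140e-02    3    2    3    2
 4.3884125429391496e-01    3    3    1    1
 3.9681905750198487e-01    3    3    2    2
-9.9714001948845998e-03    3    3    3    1
 4.1798265167483223e-01    3    3    3    3
-1.7814606774701525e+00    1    1    0    0
-1.8066268933054594e+00    2    2    0    0
 2.1255638247246283e-01    3    1    0    0
-1.3715753427299688e+00    3    3    0    0
-8.9533871947590114e+01    0    0    0    0
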