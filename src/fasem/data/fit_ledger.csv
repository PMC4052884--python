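model,chi2,df,scaling,srmsr,sbc,rmsea_upper90,cfi,tli
M0,1900,84,1.079,0.035,100055,0.121,0.888,0.791
M1,2409,97,1.071,0.056,100480,0.126,0.857,0.770
M2,1965,114,1.097,0.040,99919,0.105,0.885,0.843
M3,1673,97,1.255,0.036,99999,0.105,0.902,0.843
M4,1986,120,1.105,0.048,99909,0.102,0.884,0.850
M5,1793,133,1.251,0.050,99853,0.092,0.897,0.879
M6,968.8,107,1.217,0.046,98999,0.075,0.947,0.922
M7,967.5,111,1.225,0.046,98972,0.074,0.947,0.925
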