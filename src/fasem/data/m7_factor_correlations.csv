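group,factor,PUFA,SAT,TRANS
male,PUFA,1,0.190,-0.323
male,SAT,0.190,1,-0.160
male,TRANS,-0.323,-0.160,1
female,PUFA,1,0.249,-0.385
female,SAT,0.249,1,0.003
female,TRANS,-0.385,0.003,1
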