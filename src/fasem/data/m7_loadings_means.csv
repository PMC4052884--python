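variable,group,PUFA,SAT,TRANS,mean
C18:3n3,male,0.257,0.138,0.070,-0.186
C20:5n3,male,0.847,0,0,-0.043
C22:6n3,male,0.815,-0.373,0,0
C20:4n6,male,-0.634,-0.289,-0.215,0
C22:4n6,male,-0.837,0,0,0.168
C22:5n6,male,-0.806,0,0,0.083
C14:0,male,0,0.633,0.056,-0.221
C16:0,male,0,0.754,-0.227,0
C18:0,male,0,-0.524,0,0.072
C16:1,male,0,0.723,0,-0.209
C16:1t,male,0,0,0.499,-0.070
C18:1t,male,0,-0.114,0.888,0
C18:2t,male,0,0.248,0.728,-0.065
C18:3n3,female,0.370,0.149,0.114,0.149
C20:5n3,female,0.844,0,0,0.036
C22:6n3,female,0.801,-0.335,0,0
C20:4n6,female,-0.667,-0.285,-0.204,0
C22:4n6,female,-0.814,0,0,-0.138
C22:5n6,female,-0.788,0,0,-0.069
C14:0,female,0,0.781,0.105,0.178
C16:0,female,0,0.808,-0.290,0
C18:0,female,0,-0.681,0.084,-0.054
C16:1,female,0,0.812,0,0.169
C16:1t,female,0,0,0.540,0.057
C18:1t,female,0,-0.168,0.843,0
C18:2t,female,0,0.239,0.738,0.053
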