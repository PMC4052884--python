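variable,C18:3n3,C20:5n3,C22:6n3,C20:4n6,C22:4n6,C22:5n6,C14:0,C16:0,C18:0,C16:1,C16:1t,C18:1t,C18:2t
C18:3n3,0.832,-0.120,-0.214,0,0,0,0,0,0,0,0,0,0
C20:5n3,-0.120,0.278,0.077,0.081,0,0,0,0,0,0,0,0,0
C22:6n3,-0.214,0.077,0.372,0,0,0.137,0,0,0,0,0,0,0
C20:4n6,0,0.081,0,0.466,0,0,0,0,0,0,0,0,0
C22:4n6,0,0,0,0,0.290,0,0,0,0,0,0,0,0
C22:5n6,0,0,0.137,0,0,0.358,0,0,0,0,0,0,0
C14:0,0,0,0,0,0,0,0.437,-0.066,0.096,0,0.090,0,0
C16:0,0,0,0,0,0,0,-0.066,0.290,0,0.034,-0.115,0,0
C18:0,0,0,0,0,0,0,0.096,0,0.617,-0.080,-0.081,-0.219,-0.082
C16:1,0,0,0,0,0,0,0,0.034,-0.080,0.360,-0.099,0,0
C16:1t,0,0,0,0,0,0,0.090,-0.115,-0.081,-0.099,0.720,0,0
C18:1t,0,0,0,0,0,0,0,0,-0.219,0,0,0.220,0
C18:2t,0,0,0,0,0,0,0,0,-0.082,0,0,0,0.426
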