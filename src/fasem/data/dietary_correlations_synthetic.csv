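variable,C18:3n3,C20:5n3,C22:6n3,C20:4n6,C14:0,C16:0,C18:0,C16:1,C16:1t,C18:1t,C18:2t
C18:3n3,1,0.35,0.30,0.15,0.22,0.25,0.24,0.20,0.18,0.21,0.19
C20:5n3,0.35,1,0.92,0.20,0.12,0.14,0.13,0.11,0.10,0.09,0.08
C22:6n3,0.30,0.92,1,0.22,0.13,0.15,0.14,0.12,0.11,0.10,0.09
C20:4n6,0.15,0.20,0.22,1,0.28,0.30,0.31,0.26,0.22,0.24,0.21
C14:0,0.22,0.12,0.13,0.28,1,0.87,0.84,0.81,0.88,0.74,0.72
C16:0,0.25,0.14,0.15,0.30,0.87,1,0.78,0.83,0.82,0.75,0.73
C18:0,0.24,0.13,0.14,0.31,0.84,0.78,1,0.85,0.83,0.86,0.82
C16:1,0.20,0.11,0.12,0.26,0.81,0.83,0.85,1,0.84,0.70,0.68
C16:1t,0.18,0.10,0.11,0.22,0.88,0.82,0.83,0.84,1,0.81,0.79
C18:1t,0.21,0.09,0.10,0.24,0.74,0.75,0.86,0.70,0.81,1,0.98
C18:2t,0.19,0.08,0.09,0.21,0.72,0.73,0.82,0.68,0.79,0.98,1
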