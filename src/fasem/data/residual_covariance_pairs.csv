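var1,var2,kind,in_m7
C18:3n3,C20:5n3,biosynthesis,1
C18:3n3,C22:6n3,biosynthesis,1
C20:5n3,C20:4n6,biosynthesis,1
C22:6n3,C22:5n6,biosynthesis,1
C22:4n6,C22:5n6,biosynthesis,0
C20:5n3,C22:6n3,dietary,1
C14:0,C16:0,dietary,1
C14:0,C18:0,dietary,1
C14:0,C16:1t,dietary,1
C16:0,C16:1,dietary,1
C16:0,C16:1t,dietary,1
C18:0,C16:1,dietary,1
C18:0,C16:1t,dietary,1
C18:0,C18:1t,dietary,1
C18:0,C18:2t,dietary,1
C16:1,C16:1t,dietary,1
C14:0,C16:1,dietary,0
C16:1t,C18:1t,dietary,0
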