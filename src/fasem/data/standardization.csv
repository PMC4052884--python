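variable,common_name,family,transform,mean,sd,log_mean,log_sd,in_model
C14:0,Myristic,saturated,identity,0.31,0.08,,,1
C16:0,Palmitic,saturated,identity,21.29,1.24,,,1
C18:0,Stearic,saturated,identity,18.11,0.95,,,1
C24:0,Lignoceric,saturated,identity,0.43,0.16,,,0
C16:1,Palmitoleic,monounsaturated,identity,0.35,0.19,,,1
C18:1,Oleic,monounsaturated,identity,13.88,1.06,,,0
C20:1,Eicosenoic,monounsaturated,natural_log,0.27,0.11,,,0
C24:1,Nervonic,monounsaturated,identity,0.45,0.15,,,0
C16:1t,trans Palmitoleic,trans,identity,0.17,0.05,,,1
C18:1t,trans Oleic,trans,identity,1.62,0.55,,,1
C18:2t,trans Linoleic,trans,identity,0.25,0.08,,,1
C18:3n3,alpha-Linolenic,n3,natural_log,0.19,0.10,-6.38,0.41,1
C20:5n3,Eicosapentaenoic,n3,natural_log,0.74,0.46,-5.04,0.48,1
C22:5n3,Docosapentaenoic n3,n3,identity,2.74,0.46,,,0
C22:6n3,Docosahexaenoic,n3,identity,4.88,1.38,,,1
C18:2n6,Linoleic,n6,identity,11.19,1.74,,,0
C18:3n6,gamma-Linolenic,n6,natural_log,0.08,0.09,,,0
C20:2n6,Eicosadienoic,n6,identity,0.28,0.05,,,0
C20:3n6,Eicosatrienoic,n6,identity,1.59,0.36,,,0
C20:4n6,Arachidonic,n6,identity,16.78,1.62,,,1
C22:4n6,Docosatetraenoic,n6,identity,3.76,0.83,,,1
C22:5n6,Docosapentaenoic n6,n6,identity,0.66,0.19,,,1
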