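family,taxon,period,rate_mean,rate_se,n_sessions
Apidae,Apis mellifera,dusk,30.50,11.70,6
Apidae,Apis mellifera,night,0,0,6
Apidae,Apis mellifera,morning,5.90,1.61,6
Apidae,Xylocopa olivieri,dusk,0,0,6
Apidae,Xylocopa olivieri,night,0,0,6
Apidae,Xylocopa olivieri,morning,0.33,0.15,6
Apidae,Xylocopa violacea,dusk,0.17,0.17,6
Apidae,Xylocopa violacea,night,0,0,6
Apidae,Xylocopa violacea,morning,0.97,0.32,6
Sphingidae,Theretra alecto,dusk,0,0,6
Sphingidae,Theretra alecto,night,0.17,0.08,6
Sphingidae,Theretra alecto,morning,0.03,0.03,6
Syrphidae,Eupeodes corollae,dusk,0,0,6
Syrphidae,Eupeodes corollae,night,0,0,6
Syrphidae,Eupeodes corollae,morning,0.03,0.03,6
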