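compound_id,condition,mean_difference,sd,n,ssmd_printed,autofluorescence_note
P05E07,full,-34.4,6.0,3,-3.25,0
P02E06,full,-28.8,1.3,3,-12.58,0
P04C02,full,-27.4,5.6,3,-2.75,0
P01F03,full,-22.0,11.2,3,-1.11,0
P05C06,full,-19.9,4.6,3,-2.43,0
P01G08,full,-18.1,8.1,3,-1.26,0
P03F08,full,-17.7,3.3,3,-3.04,0
P02B03,full,-17.3,6.0,3,-1.62,0
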