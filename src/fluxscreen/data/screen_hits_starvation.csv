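compound_id,condition,mean_difference,sd,n,ssmd_printed,autofluorescence_note
P05D05,starvation,2590.4,765.1,3,1.91,1
P05C04,starvation,536.3,294.2,3,1.03,0
P02D03,starvation,336.7,182.2,3,1.04,0
P05D10,starvation,335.7,85.5,3,2.21,0
P04C10,starvation,256.2,45.0,3,3.21,0
P01B11,starvation,249.9,38.4,3,3.67,0
P03B08,starvation,243.9,45.4,3,3.03,0
P01F02,starvation,240.8,49.9,3,2.72,0
P03B06,starvation,235.2,32.0,3,4.14,0
P05B05,starvation,234.4,44.8,3,2.95,1
P01E05,starvation,224.6,19.1,3,6.65,0
P05E10,starvation,221.8,21.1,3,5.92,0
P01C06,starvation,220.6,37.8,3,3.29,0
P01F11,starvation,209.4,55.6,3,2.13,0
P01G06,starvation,174.5,21.1,3,4.67,0
P04E03,starvation,174.3,30.7,3,3.21,0
P02D05,starvation,170.9,67.0,3,1.44,0
P04E04,starvation,166.1,48.5,3,1.93,0
Arzanol,starvation,164.6,63.9,3,1.45,0
P01F08,starvation,159.6,45.8,3,1.97,0
P05B09,starvation,158.8,53.8,3,1.67,0
P01G09,starvation,158.7,52.9,3,1.69,0
P04D02,starvation,158.2,19.3,3,4.63,0
P05B06,starvation,153.1,69.7,3,1.24,0
P05B02,starvation,149.6,47.0,3,1.80,0
P05C03,starvation,149.0,32.9,3,2.55,0
P03F09,starvation,138.3,37.5,3,2.08,0
P02E04,starvation,122.0,63.9,3,1.08,0
P02F04,starvation,105.1,55.0,3,1.08,0
P04G07,starvation,98.3,29.4,3,1.88,0
P02B07,starvation,93.7,44.5,3,1.19,0
P04B04,starvation,93.4,34.7,3,1.52,0
P04B07,starvation,87.2,39.5,3,1.24,0
P04F06,starvation,78.1,19.0,3,2.32,0
P05E07,starvation,67.4,19.5,3,1.95,0
P04B02,starvation,67.1,15.6,3,2.43,0
P04G08,starvation,66.9,30.5,3,1.24,0
P02B02,starvation,60.7,25.1,3,1.36,0
P05F02,starvation,59.4,12.7,3,2.64,0
P03F08,starvation,53.3,13.2,3,2.28,0
P05F03,starvation,46.0,14.1,3,1.84,0
P01C05,starvation,41.8,16.6,3,1.42,0
P04C02,starvation,40.0,16.0,3,1.41,0
P02E08,starvation,38.7,3.4,3,6.44,0
P05E06,starvation,36.9,15.9,3,1.31,0
P04E10,starvation,35.4,17.2,3,1.16,0
P05C06,starvation,34.8,5.1,3,3.85,0
P03E07,starvation,33.6,17.6,3,1.08,0
P05D06,starvation,33.2,12.4,3,1.51,0
P05G05,starvation,33.2,2.4,3,7.93,0
P02D07,starvation,32.1,17.3,3,1.05,0
P05E04,starvation,31.3,6.8,3,2.59,0
P01G02,starvation,29.8,14.2,3,1.18,0
P04C11,starvation,27.6,5.6,3,2.76,0
P01C09,starvation,25.1,6.8,3,2.10,0
P05F04,starvation,23.8,7.2,3,1.86,0
P04B10,starvation,23.1,8.3,3,1.57,0
P05D07,starvation,22.9,5.5,3,2.36,0
P01E03,starvation,22.0,9.0,3,1.39,0
P05E02,starvation,21.1,4.0,3,3.01,0
P04E02,starvation,18.2,9.2,3,1.12,0
P04D04,starvation,17.2,8.0,3,1.21,0
P05B10,starvation,17.2,7.5,3,1.30,0
P03E06,starvation,15.9,3.5,3,2.56,0
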