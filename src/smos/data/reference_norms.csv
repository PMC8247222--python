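age_band,sex,smos_mean,smos_sd,source
total,combined,74.3,3.63,population WS/DSC studies
total,male,77.2,9.75,population WS/DSC studies
total,female,69.7,8.73,population WS/DSC studies
30-39,combined,75.9,3.90,population WS/DSC studies
30-39,male,78.6,9.59,population WS/DSC studies
30-39,female,71.2,9.20,population WS/DSC studies
40-49,combined,75.1,3.31,population WS/DSC studies
40-49,male,77.5,9.77,population WS/DSC studies
40-49,female,70.9,8.20,population WS/DSC studies
50-59,combined,73.7,4.39,population WS/DSC studies
50-59,male,76.5,9.56,population WS/DSC studies
50-59,female,68.6,9.30,population WS/DSC studies
60-69,combined,68.5,3.49,population WS/DSC studies
60-69,male,74.2,9.71,population WS/DSC studies
60-69,female,64.0,8.50,population WS/DSC studies
70+,combined,60.4,3.53,population WS/DSC studies
70+,male,65.0,10.1,population WS/DSC studies
70+,female,55.5,8.3,population WS/DSC studies
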