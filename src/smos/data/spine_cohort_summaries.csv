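age_band,sex,mean,se,n,printed_difference,printed_ci_low,printed_ci_high,printed_p
total,combined,58.7,1.68,182,-15.6,-18.90,-12.30,< .001
total,male,60.0,2.42,90,-17.2,-21.95,-12.45,< .001
total,female,57.0,2.40,92,-12.7,-17.40,-8.00,< .001
30-39,combined,66.4,4.03,32,-9.5,-17.40,-1.60,< .001
30-39,male,64.1,5.39,20,-14.5,-25.06,-3.94,< .001
30-39,female,70.2,6.03,12,-1.1,-12.83,10.83,0.689
40-49,combined,63.4,3.84,41,-11.7,-19.23,-4.17,< .001
40-49,male,59.2,5.39,24,-18.3,-28.86,-7.74,< .001
40-49,female,68.7,5.09,17,-2.2,-12.18,7.78,0.258
50-59,combined,68.8,4.35,30,-4.8,-13.42,3.62,0.348
50-59,male,75.2,6.09,14,-1.3,-13.24,10.64,0.465
50-59,female,63.3,5.91,6,-5.3,-16.84,6.26,0.023
60-69,combined,57.0,3.2,36,-11.5,-17.77,-5.23,< .001
60-69,male,54.6,4.41,17,-19.6,-28.25,-10.95,< .001
60-69,female,49.7,4.66,19,-14.3,-23.43,-5.17,< .001
70+,combined,46.7,2.42,43,-13.7,-18.45,-8.95,< .001
70+,male,49.9,3.25,16,-15.1,-21.47,-8.73,< .001
70+,female,44.9,3.33,27,-10.6,-17.13,-4.07,< .001
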