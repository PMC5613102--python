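fatty_acid,control_mean,control_se,control_letter,elovl4a_mean,elovl4a_se,elovl4a_letter,elovl4b_mean,elovl4b_se,elovl4b_letter
24:0,1.19,0.10,a,1.60,0.25,b,1.51,0.08,b
26:0,23.46,1.15,a,22.49,0.76,a,26.82,4.81,a
28:0,0.95,0.19,a,4.42,0.62,b,2.23,0.33,b
30:0,0.23,0.06,a,2.51,0.44,b,0.48,0.05,a
32:0,0.04,0.01,a,0.40,0.02,b,0.11,0.04,b
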