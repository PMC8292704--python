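programmed_mm,cycle_time_s,ct_fit_mm,ct_envelope_mm,cbct_fit_mm,abs_difference_mm
3,3,2.56,2.60,1.63,0.93
3,5,,,,
3,7,,,,
5,3,4.19,4.98,4.14,0.05
5,5,4.82,5.14,4.71,0.11
5,7,,,,
7,3,5.91,6.79,6.35,0.44
7,5,6.92,7.48,6.87,0.05
7,7,6.85,7.19,7.52,0.67
9,3,8.14,8.83,8.69,0.55
9,5,8.66,8.79,8.93,0.27
9,7,9.22,9.31,9.04,0.18
11,3,,10.64,10.89,
11,5,10.31,10.40,11.14,0.83
11,7,10.71,10.89,11.12,0.41
13,3,,12.28,13.10,
13,5,12.55,12.39,13.14,0.59
13,7,13.69,12.52,13.18,0.51
15,3,,14.36,15.07,
15,5,14.49,14.50,15.21,0.72
15,7,14.10,14.96,15.15,1.05
17,3.35,16.01,16.16,16.79,0.78
17,5,16.36,16.37,16.86,0.50
17,7,17.01,16.61,17.34,0.33
19,3.65,17.89,18.25,18.83,0.94
19,5,18.18,18.15,18.92,0.74
19,7,18.96,18.40,19.24,0.28
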