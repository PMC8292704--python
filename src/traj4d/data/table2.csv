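patient,target_diameter_cm,si_ct_mm,si_cbct_mm,si_absdiff_mm,ap_ct_mm,ap_cbct_mm,ap_absdiff_mm,lr_ct_mm,lr_cbct_mm,lr_absdiff_mm
1,3,2.8,2.0,0.8,2.8,2.5,0.3,1.0,0.5,0.5
2,3,4.0,4.1,0.1,1.1,1.5,0.4,0.7,0.8,0.2
3,1,5.5,11.6,6.2,1.4,0.9,0.5,1.2,0.6,0.7
4,1,6.0,5.0,1.0,1.9,1.0,0.9,2.1,0.6,1.5
5,3,1.5,1.6,0.1,2.2,2.4,0.3,1.6,1.3,0.3
6,2,0.9,2.4,1.6,1.8,1.8,0.1,1.1,1.7,0.6
7,3,2.1,3.1,1.0,2.7,2.9,0.3,2.9,1.2,1.7
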