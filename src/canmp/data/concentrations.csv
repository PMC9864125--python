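code,raw_mean_per100g,corrected_mean_per100g,std_error_per100g,micf_52,micf_156,micf_260,mif_52,mif_156,mif_260
D-C-1,10.00,8.10,1.53,0.32,0.97,1.62,10.13,30.40,50.66
D-D-1,5.33,4.32,0.33,0.17,0.52,0.87,5.40,16.21,27.02
D-D-2,2.67,2.16,0.33,0.09,0.26,0.43,2.70,8.11,13.51
D-D-3,16.67,13.50,2.33,0.54,1.62,2.71,16.89,50.66,84.44
D-D-4,2.67,2.16,1.33,0.09,0.26,0.43,2.70,8.11,13.51
D-D-5,6.00,4.86,0.58,0.19,0.58,0.97,6.08,18.24,30.40
D-D-6,1.33,1.08,0.33,0.04,0.13,0.22,1.35,4.05,6.76
D-D-7,7.33,5.94,1.20,0.24,0.71,1.19,7.43,22.29,37.15
D-D-8,9.33,7.56,1.76,0.30,0.91,1.52,9.46,28.37,47.29
D-D-9,5.33,4.32,0.88,0.17,0.52,0.87,5.40,16.21,27.02
D-D-10,2.67,2.16,0.88,0.09,0.26,0.43,2.70,8.11,13.51
D-D-12,6.67,5.40,0.88,0.22,0.65,1.08,6.76,20.27,33.78
D-DE-1,4.00,3.24,0.58,0.13,0.39,0.65,4.05,12.16,20.27
O-F-1,4.67,3.78,1.86,0.15,0.45,0.76,4.73,14.19,23.64
I-M-1,3.33,2.70,1.20,0.11,0.32,0.54,3.38,10.13,16.89
I-M-2,1.33,1.08,0.33,0.04,0.13,0.22,1.35,4.05,6.76
I-M-3,6.00,4.86,1.15,0.19,0.58,0.97,6.08,18.24,30.40
D-MI-1,1.33,1.08,0.33,0.04,0.13,0.22,1.35,4.05,6.76
P-P-1,4.00,3.24,1.15,0.13,0.39,0.65,4.05,12.16,20.27
P-P-2,16.00,12.96,3.21,0.52,1.56,2.60,16.21,48.64,81.06
S-SAS-1,2.00,1.62,0.58,0.06,0.19,0.32,2.03,6.08,10.13
S-SAS-2,3.33,2.70,0.67,0.11,0.32,0.54,3.38,10.13,16.89
S-SAS-3,1.00,0.81,0.50,0.03,0.10,0.16,1.01,3.04,5.07
S-SAS-4,2.67,2.16,1.33,0.09,0.26,0.43,2.70,8.11,13.51
K-SF-1,10.67,8.64,1.76,0.35,1.04,1.73,10.81,32.43,54.04
K-SF-2,14.00,11.34,3.61,0.45,1.36,2.27,14.19,42.56,70.93
K-SF-3,6.00,4.86,1.15,0.19,0.58,0.97,6.08,18.24,30.40
K-SF-4,4.67,3.78,0.67,0.15,0.45,0.76,4.73,14.19,23.64
T-T-1,16.67,13.50,0.88,0.54,1.62,2.71,16.89,50.66,84.44
K-V-1,6.00,4.86,1.53,0.19,0.58,0.97,6.08,18.24,30.40
D-W-1,2.00,1.62,0.58,0.06,0.19,0.32,2.03,6.08,10.13
I-Y-1,6.67,5.40,1.86,0.22,0.65,1.08,6.76,20.27,33.78
I-Y-2,3.33,2.70,0.33,0.11,0.32,0.54,3.38,10.13,16.89
grand,5.93,4.12,0.62,0.17,0.50,0.83,5.15,15.46,25.77
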