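name,n_control,mean_control,sd_control,n_case,mean_case,sd_case,p_value_printed,fold_change_printed,peaks
Phenylpyruvic acid,42,10.8,10.2,46,73.9,126.6,0.003,6.853,7.36:0.56872|3.85:0.379147
D-Mandelic acid,10,2.1,2.2,8,9.9,8.2,0.013,4.762,7.4:12.1951|4.3:2.43902
2-Furoylglycine,21,12.7,17.7,20,37.5,39.8,0.007,2.95,7.65:0.753769|6.6:0.753769|3.95:1.50754
Tartaric acid,51,10.3,24.2,51,27.3,26.9,0.0001,2.665,4.34:4.46097
Phenylacetic acid,42,5.5,5.6,38,13.9,14.7,0.003,2.558,7.3:5.8309|3.54:2.33236
Glycine,51,117.8,124.1,51,282.6,342.2,0.008,2.4,3.56:0.350672
Methionine,13,3.6,1.4,12,8.4,8.6,0.034,2.343,2.13:8.37209|2.64:5.5814
Acetic acid,51,8.9,7.2,51,17.2,13.3,0.001,1.931,1.92:9.02256
Phenylalanine,42,21.0,18.3,47,39.7,21.4,0.0001,1.889,7.33:4.00534|3.28:1.60214
Neopterin,51,3.0,5.3,51,5.2,7.6,0.022,1.75,8.78:7.89474|6.85:7.89474
2PY and 4PY,51,5.9,3.5,51,10.1,5.3,0.0001,1.728,8.25:4.5283|6.65:4.5283|3.9:13.5849
L-Citramalic acid,51,18.5,12.0,51,31.8,24.9,0.004,1.721,2.7:1.92771|1.35:2.89157
Maleic acid,50,1.1,1.9,51,1.7,2.2,0.0001,1.639,6.3:54.5455
Adenine,45,2.0,2.0,50,3.2,3.7,0.03,1.57,8.2:32.4324
1-Methylnicotinamide,51,9.4,9.0,51,13.6,16.0,0.027,1.459,9.28:1.25|8.9:2.5|4.48:3.75
2-Hydroxyisovaleric acid,36,1.2,0.7,31,1.7,1.1,0.01,1.459,0.85:93.5065|3.86:15.5844
Oxaloacetic acid,50,27.8,26.9,47,38.8,25.1,0.008,1.396,3.68:4.46097
3-Methylglutaconic acid,51,5.6,2.9,51,7.8,4.4,0.003,1.392,2.05:16.3636|3.35:10.9091
Valine,51,4.6,2.9,51,6.4,5.2,0.011,1.392,0.99:17.3077|2.28:2.88462|3.61:2.88462
Acetoacetic acid,46,11.8,9.9,48,16.1,8.5,0.006,1.371,2.29:7.27273|3.45:4.84848
Guanidinoacetic acid,51,93.1,71.5,50,74.1,67.7,0.026,0.796,3.8:1.67832
Creatine,49,201.4,370.1,49,160.2,269.7,0.031,0.796,2.9:0.194542|3.93:0.129695
Dimethylamine,51,40.2,27.2,51,30.3,20.6,0.041,0.753,2.72:4.41176
Allantoin,51,16.2,11.3,48,7.1,5.9,0.0001,0.44,5.4:5.30973|6.15:5.30973
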