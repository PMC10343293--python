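name,mean,sd,peaks
null_01,2.343,0.95,4.25:1.5311|0.918:3.0622|6.317:3.82775
null_02,6.055,10.193,3.979:0.784852
null_03,79.047,82.659,2.184:0.0967832
null_04,182.516,327.766,1.87:0.0110944|2.702:0.0110944|6.589:0.00221888
null_05,130.818,62.136,7.526:0.0965624|8.893:0.0321875
null_06,134.15,87.743,7.958:0.0521002|8.68:0.0390752
null_07,7.96,14.45,8.132:0.276817|4.218:0.138408|8.656:0.138408
null_08,67.223,137.34,8.425:0.00970827|6.792:0.0485413
null_09,169.577,104.737,3.849:0.0763818
null_10,4.036,5.589,1.576:1.43138
null_11,76.254,56.638,3.236:0.141248
null_12,134.796,306.064,9.308:0.0261383
null_13,56.344,35.428,3.841:0.22581
null_14,6.496,3.079,4.262:2.59825
null_15,14.756,30.275,6.18:0.165153|4.229:0.0990917
null_16,2.331,2.727,6.765:2.93363
null_17,29.077,37.026,3.526:0.0648193|2.663:0.0864258|1.044:0.0648193
null_18,24.502,38.675,9.218:0.137901|3.454:0.0689507
null_19,134.345,312.897,6.538:0.00958782|6.497:0.00639188|8.68:0.00958782
null_20,1.347,1.517,2.29:1.75786|2.091:1.75786|7.679:1.75786
null_21,5.374,9.211,3.642:0.868527
null_22,13.025,14.498,7.961:0.41385|6.492:0.13795
null_23,24.328,49.353,7.896:0.162098
null_24,13.611,6.629,3.96:0.603409|6.521:0.502841|6.085:0.100568
null_25,5.667,2.423,3.26:3.30169
null_26,6.549,13.936,0.859:0.287026|8.883:0.287026
null_27,3.631,7.275,3.708:0.219931|3.386:0.549828|8.014:0.329897
null_28,7.255,6.879,0.666:1.16296
null_29,4.506,5.571,7.183:0.783277|8.693:0.652731
null_30,7.416,6.857,6.254:1.16669
null_31,29.593,30.749,1.649:0.111502|6.196:0.0929182|1.687:0.0557509
null_32,2.086,3.285,1.906:1.10696|3.96:1.10696|6.462:0.221392
null_33,3.808,4.554,1.634:0.405392|8.275:0.810783|6.301:0.540522
null_34,4.673,3.31,4.015:2.41692
null_35,107.121,196.994,1.343:0.0174044|8.644:0.0232059
null_36,3.154,7.345,2.716:1.08918
null_37,9.897,18.784,2.702:0.0608421|6.204:0.121684|6.514:0.243368
null_38,7.445,9.472,3.717:0.844595
null_39,42.255,22.919,2.032:0.0775679|7.424:0.0387839|1.168:0.232704
null_40,1.501,2.301,1.206:2.31783|6.296:1.15892
null_41,9.478,4.512,6.427:0.633232|8.388:0.379939|3.951:0.759878
null_42,59.875,59.025,0.65:0.0193623|6.344:0.116174
null_43,4.717,3.489,1.103:0.229292|8.592:0.917168|6.206:1.14646
null_44,6.595,9.478,7.492:0.42203|0.811:0.42203
null_45,94.749,198.509,8.275:0.0403004
null_46,29.943,50.698,6.318:0.157797
null_47,1.746,1.214,7.66:2.1966|8.111:4.39319
null_48,13.658,6.49,9.096:1.23267
null_49,21.693,35.401,1.066:0.225982
null_50,4.502,10.555,4.176:0.757935
null_51,31.614,41.479,6.35:0.137763|3.972:0.0551053
null_52,54.161,90.547,8.161:0.0883519
null_53,3.281,6.597,2.902:0.727603|8.491:0.485069
null_54,100.578,194.604,8.577:0.0205546|0.718:0.013703|2.785:0.00685152
null_55,2.493,1.591,0.787:5.02828
null_56,8.0,11.845,9.207:0.168848|8.261:0.253271|8.95:0.253271
null_57,65.089,57.762,3.292:0.0461665|2.041:0.0923329
null_58,39.309,80.04,9.043:0.0666333|3.283:0.0333167
null_59,26.065,31.237,3.354:0.128053|6.638:0.128053
null_60,1.188,1.996,8.387:4.00802
null_61,122.141,186.027,6.149:0.0215023|8.569:0.00430045|7.994:0.0172018
null_62,2.549,2.69,3.495:2.97398
null_63,43.446,47.446,6.348:0.112408|3.868:0.0374695|2.128:0.0187347
null_64,11.321,11.407,1.92:0.701324
null_65,5.81,9.482,4.32:0.421852|7.333:0.316389|9.321:0.105463
null_66,53.728,94.199,1.767:0.0141544|8.245:0.0707722
null_67,4.012,3.111,7.164:1.54291|4.189:1.02861
null_68,65.489,93.832,8.534:0.0426294|3.793:0.0426294
null_69,7.487,8.451,6.884:0.946634
null_70,2.664,3.188,3.891:2.50941
null_71,6.833,5.78,1.576:0.754954|0.842:0.629129
null_72,188.176,132.302,6.824:0.0403118|0.764:0.0201559
null_73,5.019,10.836,3.523:0.73828
null_74,1.115,1.566,1.313:3.19285|1.02:1.91571
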