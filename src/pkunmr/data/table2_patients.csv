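patient_id,phe_serum,gpv,phenotype,allele1,allele2,sapropterin,protein_intake
404,305,0,cPKU,IVS12+1G>A,p.R408W,no,0.420
397,289,0,cPKU,p.R408W,p.E280K,no,0.330
385,325,,mPKU,IVS12+1G>A,p.F410I,no,0.320
369,500,5.1,mPKU,IVS12+1G>A,p.Y414C,no,0.230
363,132,,mPKU,IVS10-11G>A,,no,0.500
362,597,0,cPKU,p.R408W,p.R408W,no,0.240
359,467,0,cPKU,IVS10-11G>A,p.Y386C,no,0.300
356,287,5.1,mPKU,p.Y356X,p.Y414C,yes,1.101
405,429,0,cPKU,IVS12+1G>A,p.R408W,no,0.290
339,303,0,cPKU,IVS12+1G>A,p.R408W,no,0.440
347,279,0,cPKU,IVS12+1G>A,IVS10-11G>A,no,0.200
342,344,5.0,mPKU,p.R408W,p.D129Y,yes,1.700
336,135,0,cPKU,IVS12+1G>A,p.R408W,no,0.401
334,431,5.1,mPKU,p.G46S,p.Y414C,yes,2.700
335,475,5.1,mPKU,p.G46S,p.Y414C,yes,2.400
323,261,5.1,mPKU,p.F39L,p.Y414C,yes,1.102
316,528,5.1,mPKU,IVS12+1G>A,p.Y414C,no,0.390
314,546,0,cPKU,p.R408W,p.T266E,no,0.180
333,36,0,cPKU,p.R252W,p.R252W,no,0.100
313,254,5.1,mPKU,p.Y414C,p.W120X,yes,0.501
306,692,0,cPKU,p.R158Q,IVS12+1G>A,no,0.400
298,533,5.1,mPKU,p.R408W,p.Y414C,yes,0.320
302,513,0,cPKU,IVS10nt-11G>A,c.-473-?_168+?du,no,0.070
295,627,0,cPKU,IVS12+1G>A,p.P281L,no,0.070
292,434,0,cPKU,IVS12+1G>A,IVS12+1G>A,no,0.180
282,392,0,cPKU,IVS12+1G>A,IVS10-11G>A,no,0.200
278,622,6.9,mPKU,p.R408W,p.E390G,no,1.290
254,327,2.0,cPKU,p.L48S,IVS12+1G>A,yes,0.620
253,968,0,cPKU,IVS12+1G>A,E221D222duAG,no,0.110
258,682,0,cPKU,IVS12+1G>A,p.R408W,no,0.230
249,840,0,cPKU,IVS12+1G>A,p.R408W,no,0.250
236,1504,0,cPKU,IVS10-11G>A,p.Y386C,no,0.550
242,700,1.1,cPKU,IVS12+1G>A,p.I65T,yes,0.460
272,1010,0,cPKU,IVS10-11G>A,p.R408W,no,0.301
243,969,0,cPKU,IVS12+1G>A,p.R252W,no,0.502
237,277,0,cPKU,p.R408W,p.R408W,no,0.290
238,984,0,cPKU,IVS12+1G>A,IVS12+1G>A,no,0.120
235,1175,,cPKU,IVS12+1G>A,,no,0.220
211,468,2.6,cPKU,p.R408W,p.A104D,yes,0.490
212,1163,0,cPKU,IVS10-11G>A,p.R408W,no,0.302
196,1292,0,cPKU,IVS12+1G>A,p.E221D,no,0.750
190,869,0,cPKU,p.P281L,p.R243X,no,1.103
191,766,0,cPKU,IVS12+1G>A,p.R408W,no,0.440
176,83,0,mPKU,IVS12+1G>A,p.R408W,no,0.180
168,831,,cPKU,,,no,0.230
143,1590,,cPKU,IVS12+1G>A,,no,1.200
145,1344,2.6,cPKU,IVS1+5G>T,p.A104D,no,1.000
137,1118,5.1,mPKU,IVS12+1G>A,p.Y414C,no,1.100
129,1613,,cPKU,IVS12+1G>A,,no,0.600
126,1955,0,cPKU,IVS12+1G>A,p.D282N,no,0.800
121,1390,0,cPKU,IVS12+1G>A,p.R158Q,no,1.104
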