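model_id,tp,tn,fp,fn
AlxNet,143,287722,4252,1487
DnsNet_121,445,289534,2440,1185
DnsNet_161,424,290306,1668,1206
DnsNet_169,303,290123,1851,1327
Inc_Res_v2,767,290417,1557,863
Inc_v1,270,291069,905,1360
Inc_v2,430,288975,2999,1200
Inc_v3,660,288636,3338,970
Inc_v4,783,289716,2258,847
Mob_v1_0.25,77,290337,1637,1553
Mob_v1_0.50,206,290511,1463,1424
Mob_v1_0.75,262,289403,2571,1368
Mob_v1_1.0,316,286020,5954,1314
Mob_v2_0.35,164,289551,2423,1466
Mob_v2_0.50,229,289190,2784,1401
Mob_v2_0.75,286,289899,2075,1344
Mob_v2_1.0,368,289669,2305,1262
Mob_v2_1.3,310,290706,1268,1320
Mob_v2_1.4,393,286262,5712,1237
Mob_v3_lrg,277,287333,4641,1353
Mob_v3_lrgm,226,289858,2116,1404
Mob_v3_sml,152,290222,1752,1478
Mob_v3_smlm,116,289739,2235,1514
Ns_lrg,861,289178,2796,769
Ns_mob,372,290775,1199,1258
Pns_lrg,900,289679,2295,730
Pns_mob,381,290484,1490,1249
Rs_v1_50,244,290113,1861,1386
Rs_v1_101,288,289712,2262,1342
Rs_v1_152,383,289076,2898,1247
Rs_v2_50,310,290951,1023,1320
Rs_v2_101,272,290901,1073,1358
Rs_v2_152,406,289753,2221,1224
Vgg_16,276,288835,3139,1354
Vgg_19,275,289677,2297,1355
Xcp_v1,681,287741,4233,949
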