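model_id,TPR,TNR,PPV,ACC,ERR,BAC,GM,YI,DP,F1,MCC,KAPPA
AlxNet,0.08773,0.98544,0.03254,0.98045,0.01955,0.53658,0.294028,0.073167,0.448681,0.04747,0.04477,0.03969
DnsNet_121,0.27301,0.99164,0.15425,0.98765,0.01235,0.63232,0.520312,0.264649,0.909576,0.19712,0.19935,0.19138
DnsNet_161,0.26012,0.99429,0.20268,0.99021,0.00979,0.62720,0.508563,0.254410,0.985547,0.22783,0.22475,0.22299
DnsNet_169,0.18589,0.99366,0.14067,0.98918,0.01082,0.58977,0.429780,0.179550,0.857060,0.16015,0.15633,0.15481
Inc_Res_v2,0.47055,0.99467,0.33003,0.99176,0.00824,0.73261,0.684137,0.465219,1.224305,0.38796,0.39008,0.38394
Inc_v1,0.16564,0.99690,0.22979,0.99229,0.00771,0.58127,0.406363,0.162545,0.995748,0.19251,0.19130,0.18874
Inc_v2,0.26380,0.98973,0.12540,0.98570,0.01430,0.62677,0.510974,0.253532,0.848468,0.16999,0.17534,0.16370
Inc_v3,0.40491,0.98857,0.16508,0.98533,0.01467,0.69674,0.632676,0.393475,0.976147,0.23454,0.25227,0.22846
Inc_v4,0.48037,0.99227,0.25748,0.98942,0.01058,0.73632,0.690401,0.472635,1.144106,0.33526,0.34687,0.33042
Mob_v1_0.25,0.04724,0.99439,0.04492,0.98914,0.01086,0.52082,0.216736,0.041633,0.520814,0.04605,0.04061,0.04059
Mob_v1_0.50,0.12638,0.99499,0.12343,0.99017,0.00983,0.56068,0.354608,0.121370,0.804397,0.12489,0.11995,0.11994
Mob_v1_0.75,0.16074,0.99119,0.09248,0.98658,0.01342,0.57597,0.399150,0.151931,0.735634,0.11741,0.11548,0.11115
Mob_v1_1.0,0.19387,0.97961,0.05040,0.97525,0.02475,0.58674,0.435789,0.173473,0.586183,0.08000,0.08916,0.07182
Mob_v2_0.35,0.10061,0.99170,0.06339,0.98675,0.01325,0.54616,0.315877,0.092315,0.621156,0.07778,0.07340,0.07146
Mob_v2_0.50,0.14049,0.99046,0.07600,0.98575,0.01425,0.56548,0.373030,0.130956,0.678430,0.09864,0.09655,0.09210
Mob_v2_0.75,0.17546,0.99289,0.12114,0.98836,0.01164,0.58418,0.417389,0.168353,0.812627,0.14332,0.14006,0.13766
Mob_v2_1.0,0.22577,0.99211,0.13767,0.98785,0.01215,0.60894,0.473270,0.217872,0.862727,0.17104,0.17044,0.16529
Mob_v2_1.3,0.19018,0.99566,0.19645,0.99119,0.00881,0.59292,0.435153,0.185841,0.954902,0.19327,0.18886,0.18884
Mob_v2_1.4,0.24110,0.98044,0.06437,0.97633,0.02367,0.61077,0.486197,0.221541,0.663033,0.10162,0.11536,0.09367
Mob_v3_lrg,0.16994,0.98410,0.05632,0.97958,0.02042,0.57702,0.408947,0.154043,0.608400,0.08461,0.08919,0.07691
Mob_v3_lrgm,0.13865,0.99275,0.09650,0.98801,0.01199,0.56570,0.371006,0.131403,0.741037,0.11380,0.10976,0.10796
Mob_v3_sml,0.09325,0.99400,0.07983,0.98900,0.01100,0.54363,0.304454,0.087251,0.679232,0.08602,0.08077,0.08052
Mob_v3_smlm,0.07116,0.99234,0.04934,0.98723,0.01277,0.53176,0.265746,0.063511,0.549988,0.05828,0.05295,0.05206
Ns_lrg,0.52822,0.99042,0.23544,0.98786,0.01214,0.75932,0.723300,0.518645,1.138357,0.32570,0.34747,0.32049
Ns_mob,0.22822,0.99589,0.23679,0.99163,0.00837,0.61206,0.476743,0.224114,1.023565,0.23243,0.22826,0.22822
Pns_lrg,0.55215,0.99214,0.28169,0.98970,0.01030,0.77214,0.740140,0.544287,1.209156,0.37306,0.38981,0.36841
Pns_mob,0.23374,0.99490,0.20363,0.99067,0.00933,0.61432,0.482234,0.228639,0.978718,0.21765,0.21349,0.21298
Rs_v1_50,0.14969,0.99363,0.11591,0.98894,0.01106,0.57166,0.385667,0.143319,0.793460,0.13066,0.12622,0.12518
Rs_v1_101,0.17669,0.99225,0.11294,0.98772,0.01228,0.58447,0.418710,0.168940,0.793827,0.13780,0.13528,0.13192
Rs_v1_152,0.23497,0.99007,0.11673,0.98588,0.01412,0.61252,0.482325,0.225044,0.819826,0.15598,0.15907,0.14967
Rs_v2_50,0.19018,0.99650,0.23256,0.99202,0.00798,0.59334,0.435336,0.186680,1.006538,0.20925,0.20633,0.20528
Rs_v2_101,0.16687,0.99633,0.20223,0.99172,0.00828,0.58160,0.407747,0.163196,0.956939,0.18286,0.17957,0.17873
Rs_v2_152,0.24908,0.99239,0.15455,0.98827,0.01173,0.62074,0.497177,0.241473,0.902555,0.19074,0.19054,0.18516
Vgg_16,0.16933,0.98925,0.08082,0.98470,0.01530,0.57929,0.409273,0.158574,0.702280,0.10942,0.10989,0.10267
Vgg_19,0.16871,0.99213,0.10692,0.98756,0.01244,0.58042,0.409126,0.160845,0.776746,0.13089,0.12825,0.12494
Xcp_v1,0.41779,0.98550,0.13858,0.98235,0.01765,0.70165,0.641665,0.403294,0.931244,0.20813,0.23359,0.20147
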