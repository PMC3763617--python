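# Published age- and sex-structure of the projected population of Bangladesh
# (thousands), 2001 base and 2006-2051 horizon; used only for internal
# consistency checks, never as a fitting target.
age_group,sex,2001,2006,2011,2016,2021,2026,2031,2036,2041,2046,2051
all_ages,persons,123851,133436,143515,154212,164899,174494,182384,188577,193432,196933,198964
all_ages,male,63895,68699,73700,78957,84267,88942,92739,95687,97989,99671,100682
all_ages,female,59956,64737,69815,75255,80632,85552,89645,92890,95443,97262,98282
0-4,male,8362,6711,6722,7158,7408,7173,6717,6386,6272,6210,6099
0-4,female,7724,6326,6361,6805,7008,6817,6383,6068,5960,5902,5796
5-9,male,8822,8189,6623,6646,7088,7335,7102,6651,6323,6210,6149
5-9,female,7956,7533,6234,6290,6728,6940,6750,6322,6009,5902,5844
10-14,male,8421,8779,8163,6605,6629,7070,7318,7084,6634,6307,6194
10-14,female,7432,7914,7510,6220,6276,6715,6926,6736,6308,5997,5890
15-19,male,6292,8391,8759,8145,6593,6617,7057,7304,7072,6622,6296
15-19,female,5672,7404,7897,7498,6210,6267,6705,6916,6727,6299,5989
20-24,male,4859,6265,8368,8737,8127,6578,6602,7041,7287,7056,6608
20-24,female,6057,5644,7384,7880,7482,6199,6256,6693,6905,6715,6288
25-29,male,4895,4834,6243,8340,8711,8103,6559,6583,7020,7266,7035
25-29,female,5865,6023,5626,7366,7861,7466,6185,6242,6679,6888,6700
30-34,male,4313,4863,4812,6218,8310,8679,8074,6535,6559,6995,7239
30-34,female,4436,5825,5999,5609,7343,7839,7445,6168,6224,6660,6869
35-39,male,4204,4276,4835,4786,6188,8269,8637,8034,6503,6527,6961
35-39,female,3795,4397,5794,5973,5585,7315,7809,7416,6145,6201,6634
40-44,male,3426,4149,4235,4793,4749,6140,8206,8570,7973,6453,6477
40-44,female,2774,3749,4362,5756,5935,5552,7273,7764,7373,6109,6165
45-49,male,2610,3356,4085,4175,4731,4688,6060,8099,8459,7869,6369
45-49,female,1991,2727,3705,4318,5698,5880,5502,7206,7692,7306,6053
50-54,male,2175,2521,3266,3984,4079,4622,4580,5921,7913,8265,7688
50-54,female,1826,1937,2673,3642,4244,5608,5787,5415,7093,7571,7191
55-59,male,1309,2055,2408,3128,3825,3916,4437,4397,5685,7597,7935
55-59,female,1047,1746,1872,2595,3534,4128,5455,5629,5267,6898,7364
60-64,male,1529,1194,1902,2238,2917,3567,3652,4138,4100,5301,7084
60-64,female,1299,971,1646,1777,2464,3366,3931,5195,5360,5015,6569
65-69,male,814,1320,1052,1687,1995,2601,3180,3257,3690,3656,4727
65-69,female,629,1148,880,1505,1625,2263,3093,3612,4773,4926,4609
70-74,male,926,650,1086,872,1409,1666,2173,2657,2720,3082,3054
70-74,female,699,515,974,757,1296,1409,1963,2682,3133,4140,4272
75-79,male,358,663,484,816,662,1070,1266,1650,2018,2066,2341
75-79,female,258,511,396,764,593,1028,1118,1557,2128,2486,3285
80+,male,580,483,657,629,846,848,1119,1380,1761,2189,2426
80+,female,496,367,502,500,750,760,1064,1269,1667,2247,2765
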