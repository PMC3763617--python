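# Population of Bangladesh by 5-year age group and sex, 2001 census base
# year (thousands).
age_group,sex,population_thousands
0-4,male,8362
0-4,female,7724
5-9,male,8822
5-9,female,7956
10-14,male,8421
10-14,female,7432
15-19,male,6292
15-19,female,5672
20-24,male,4859
20-24,female,6057
25-29,male,4895
25-29,female,5865
30-34,male,4313
30-34,female,4436
35-39,male,4204
35-39,female,3795
40-44,male,3426
40-44,female,2774
45-49,male,2610
45-49,female,1991
50-54,male,2175
50-54,female,1826
55-59,male,1309
55-59,female,1047
60-64,male,1529
60-64,female,1299
65-69,male,814
65-69,female,629
70-74,male,926
70-74,female,699
75-79,male,358
75-79,female,258
80+,male,580
80+,female,496
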