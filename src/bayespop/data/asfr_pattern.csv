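# Synthetic illustrative age pattern of fertility (proportions of the TFR by
# 5-year maternal age group). NOT estimated from survey data; edit or replace
# with an observed base-year pattern before substantive use.
age_group,weight
15-19,0.12
20-24,0.27
25-29,0.24
30-34,0.17
35-39,0.11
40-44,0.06
45-49,0.03
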