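# Synthetic standard survivorship schedule (NOT from any published life table).
# Smooth l(x) column with a South-Asian-type age pattern, used as the Brass-logit
# relational standard; replace this file to use a genuine model life table.
# m80 (central death rate in the open 80+ interval) is given on the age-80 row only.
age,lx_male,lx_female,m80_male,m80_female
0,1.000000,1.000000,,
1,0.925000,0.935000,,
5,0.892625,0.906950,,
10,0.881914,0.896974,,
15,0.874858,0.890695,,
20,0.866110,0.882678,,
25,0.854850,0.872969,,
30,0.842882,0.862493,,
35,0.829396,0.850418,,
40,0.813638,0.835961,,
45,0.794110,0.818406,,
50,0.768699,0.795491,,
55,0.733339,0.763671,,
60,0.684938,0.719378,,
65,0.617129,0.656073,,
70,0.527029,0.570127,,
75,0.413190,0.458382,,
80,0.285101,0.327743,0.2,0.18
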