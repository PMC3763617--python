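# Total fertility rate, Bangladesh, 1991-2001 (Bangladesh Bureau of Statistics,
# Statistical Pocket Book 2001-2007).
year,tfr
1991,4.24
1992,4.18
1993,3.84
1994,3.58
1995,3.45
1996,3.41
1997,3.10
1998,2.98
1999,2.64
2000,2.59
2001,2.56
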