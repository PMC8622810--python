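option,rating,label
1,1,excluded
1,2,excluded
1,3,excluded
1,4,excluded
1,5,FA
1,6,FA
1,7,FA
2,1,excluded
2,2,excluded
2,3,excluded
2,4,excluded
2,5,FA
2,6,FA
2,7,FA
3,1,MW
3,2,MW
3,3,MW
3,4,excluded
3,5,excluded
3,6,excluded
3,7,excluded
4,1,MW
4,2,MW
4,3,MW
4,4,excluded
4,5,excluded
4,6,excluded
4,7,excluded
5,1,MW
5,2,MW
5,3,MW
5,4,excluded
5,5,FA
5,6,FA
5,7,FA
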