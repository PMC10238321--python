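brand,tissue,printed,status
1,chest,23.9953,ok
1,thigh,018.65821,ok
1,liver,0.023366,ok
2,chest,15.939628,ok
2,thigh,8.4238238,ok
2,liver,0.0365968,ok
3,chest,19.88135,ok
3,thigh,26.60327,ok
3,liver,0.048643,ok
4,chest,32.60215,anomaly
4,thigh,17.68384,ok
4,liver,0.052834,ok
5,chest,25.27498,ok
5,thigh,23.51065,ok
5,liver,0.040853,ok
6,chest,17.9558,ok
6,thigh,14.50676,ok
6,liver,0.038176,ok
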