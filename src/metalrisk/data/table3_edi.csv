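brand,tissue,metal,printed,status
1,chest,Al,6.51,ok
1,thigh,Al,7.23,ok
1,liver,Al,0.0084,ok
2,chest,Al,4.86,ok
2,thigh,Al,3.23,ok
2,liver,Al,0.0137,ok
3,chest,Al,6.98,ok
3,thigh,Al,10.46,ok
3,liver,Al,0.018,ok
4,chest,Al,12.41,ok
4,thigh,Al,6.83,ok
4,liver,Al,0.02,ok
5,chest,Al,9.23,ok
5,thigh,Al,9.23,ok
5,liver,Al,0.015,ok
6,chest,Al,6.18,ok
6,thigh,Al,5.65,ok
6,liver,Al,0.0143,anomaly
1,chest,Cd,0.03,ok
1,thigh,Cd,00.029,ok
1,liver,Cd,0.000148,ok
2,chest,Cd,0.0079,ok
2,thigh,Cd,0.0496,ok
2,liver,Cd,0.0000528,ok
3,chest,Cd,0.0163,ok
3,thigh,Cd,0.0107,ok
3,liver,Cd,0.0000671,ok
4,chest,Cd,0.0175,ok
4,thigh,Cd,0.014,ok
4,liver,Cd,0.0000585,ok
5,chest,Cd,0.0135,ok
5,thigh,Cd,0.00847,ok
5,liver,Cd,0.000038,ok
6,chest,Cd,0.0203,ok
6,thigh,Cd,0.0135,ok
6,liver,Cd,0.0000557,ok
1,chest,Pb,1.455,ok
1,thigh,Pb,0.611,ok
1,liver,Pb,0.000208,ok
2,chest,Pb,1.779,recovered
2,thigh,Pb,0.188,ok
2,liver,Pb,0.00136,ok
3,chest,Pb,1.49,anomaly
3,thigh,Pb,0.448,ok
3,liver,Pb,0.00133,ok
4,chest,Pb,1.46,ok
4,thigh,Pb,0.566,ok
4,liver,Pb,0.000941,ok
5,chest,Pb,1.86,ok
5,thigh,Pb,0.411,ok
5,liver,Pb,0.00104,ok
6,chest,Pb,3.13,ok
6,thigh,Pb,0.296,ok
6,liver,Pb,0.00095,ok
1,chest,Ba,3.51,ok
1,thigh,Ba,2.82,ok
1,liver,Ba,0.00148,ok
2,chest,Ba,1.59,ok
2,thigh,Ba,1.816,ok
2,liver,Ba,0.00624,ok
3,chest,Ba,1.6,ok
3,thigh,Ba,03.828,ok
3,liver,Ba,0.00446,ok
4,chest,Ba,1.423,ok
4,thigh,Ba,3.139,ok
4,liver,Ba,0.00015,anomaly
5,chest,Ba,1.813,ok
5,thigh,Ba,1.994,ok
5,liver,Ba,0.00218,ok
6,chest,Ba,1.11,ok
6,thigh,Ba,2.344,ok
6,liver,Ba,0.00630,ok
1,chest,Bi,1.99,ok
1,thigh,Bi,0.00355,ok
1,liver,Bi,0.0000157,ok
2,chest,Bi,0.769,ok
2,thigh,Bi,0.00242,ok
2,liver,Bi,0.0000147,ok
3,chest,Bi,0.492,ok
3,thigh,Bi,0.00389,ok
3,liver,Bi,0.0000152,ok
4,chest,Bi,0.331,ok
4,thigh,Bi,0.00751,ok
4,liver,Bi,0.0000131,anomaly
5,chest,Bi,0.406,ok
5,thigh,Bi,0.00299,ok
5,liver,Bi,0.00000142,ok
6,chest,Bi,0.387,ok
6,thigh,Bi,0.00474,ok
6,liver,Bi,0.0000145,ok
1,chest,Co,0.031,ok
1,thigh,Co,00.022,ok
1,liver,Co,00.0000642,ok
2,chest,Co,0.0293,ok
2,thigh,Co,0.0079,ok
2,liver,Co,00.0000757,ok
3,chest,Co,0.0288,ok
3,thigh,Co,0.022,ok
3,liver,Co,00.0000571,ok
4,chest,Co,0.0468,ok
4,thigh,Co,0.0208,ok
4,liver,Co,0.0000657,ok
5,chest,Co,0.022,ok
5,thigh,Co,00.0186,ok
5,liver,Co,0.00004,ok
6,chest,Co,0.0378,ok
6,thigh,Co,0.0118,ok
6,liver,Co,0.0000414,ok
1,chest,Ni,0.128,ok
1,thigh,Ni,0.144,ok
1,liver,Ni,0.00031,ok
2,chest,Ni,0.086,ok
2,thigh,Ni,0.0807,ok
2,liver,Ni,0.00016,ok
3,chest,Ni,0.0999,ok
3,thigh,Ni,0.0886,ok
3,liver,Ni,0.000247,ok
4,chest,Ni,0.1016,ok
4,thigh,Ni,0.0818,ok
4,liver,Ni,0.000268,ok
5,chest,Ni,0.102,ok
5,thigh,Ni,0.106,ok
5,liver,Ni,0.000248,ok
6,chest,Ni,0.12,ok
6,thigh,Ni,00.092,ok
6,liver,Ni,00.000255,ok
1,chest,Cr,0.343,ok
1,thigh,Cr,0.259,ok
1,liver,Cr,0.000674,ok
2,chest,Cr,1.25,ok
2,thigh,Cr,0.1,ok
2,liver,Cr,000.00023,ok
3,chest,Cr,0.159,ok
3,thigh,Cr,0.102,ok
3,liver,Cr,0.000267,ok
4,chest,Cr,0.15,ok
4,thigh,Cr,00.133,ok
4,liver,Cr,0.00203,ok
5,chest,Cr,0.15,ok
5,thigh,Cr,00.096,ok
5,liver,Cr,00.000274,ok
6,chest,Cr,0.167,ok
6,thigh,Cr,0.132,ok
6,liver,Cr,0.000287,ok
1,chest,Fe,12.89,ok
1,thigh,Fe,10.14,ok
1,liver,Fe,0.05459,ok
2,chest,Fe,4.921,recovered
2,thigh,Fe,2.588,ok
2,liver,Fe,0.0551,ok
3,chest,Fe,12.015,ok
3,thigh,Fe,8.68,ok
3,liver,Fe,00.0611,ok
4,chest,Fe,4.309,ok
4,thigh,Fe,10.368,ok
4,liver,Fe,0.06877,ok
5,chest,Fe,4.667,ok
5,thigh,Fe,3.447,ok
5,liver,Fe,0.0345,ok
6,chest,Fe,017.84,ok
6,thigh,Fe,6.079,ok
6,liver,Fe,0.04374,ok
1,chest,Cu,0.5381,ok
1,thigh,Cu,0.4551,ok
1,liver,Cu,0.005868,ok
2,chest,Cu,0.424,ok
2,thigh,Cu,0.411,ok
2,liver,Cu,0.0046,ok
3,chest,Cu,00.558,ok
3,thigh,Cu,0.342,ok
3,liver,Cu,0.00496,ok
4,chest,Cu,0.42,ok
4,thigh,Cu,00.8,ok
4,liver,Cu,000.00535,ok
5,chest,Cu,0.406,ok
5,thigh,Cu,0.469,ok
5,liver,Cu,0.0044,ok
6,chest,Cu,00.4156,ok
6,thigh,Cu,0.3557,ok
6,liver,Cu,0.00438,ok
1,chest,Zn,6.36,ok
1,thigh,Zn,09.753,ok
1,liver,Zn,0.0456,ok
2,chest,Zn,4.987,ok
2,thigh,Zn,8.829,ok
2,liver,Zn,0.0327,ok
3,chest,Zn,4.496,ok
3,thigh,Zn,8.567,ok
3,liver,Zn,0.0337,ok
4,chest,Zn,7.816,ok
4,thigh,Zn,11.368,ok
4,liver,Zn,0.03623,ok
5,chest,Zn,8.637,ok
5,thigh,Zn,12.87,ok
5,liver,Zn,00.0355,ok
6,chest,Zn,5.7629,ok
6,thigh,Zn,10.9317,ok
6,liver,Zn,0.03713,ok
1,chest,Se,0.189,ok
1,thigh,Se,0.216,ok
1,liver,Se,0.00116,ok
2,chest,Se,0.1349,ok
2,thigh,Se,0.1084,ok
2,liver,Se,0.0008957,ok
3,chest,Se,0.158,ok
3,thigh,Se,0.132,ok
3,liver,Se,0.000858,ok
4,chest,Se,0.16,ok
4,thigh,Se,00.2128,ok
4,liver,Se,0.001005,ok
5,chest,Se,0.156,ok
5,thigh,Se,0.133,ok
5,liver,Se,0.000941,ok
6,chest,Se,0.1519,ok
6,thigh,Se,0.1152,ok
6,liver,Se,0.000861,ok
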