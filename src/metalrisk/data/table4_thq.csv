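brand,tissue,metal,printed,status
1,chest,Al,16.275,ok
1,thigh,Al,18.075,ok
1,liver,Al,0.021,ok
2,chest,Al,012.155,ok
2,thigh,Al,8.08812,ok
2,liver,Al,0.03441,ok
3,chest,Al,17.451,ok
3,thigh,Al,026.1646,ok
3,liver,Al,0.04647,ok
4,chest,Al,31.025,ok
4,thigh,Al,17.084,ok
4,liver,Al,0.050017,ok
5,chest,Al,23.09257,ok
5,thigh,Al,23.09257,ok
5,liver,Al,0.039053,ok
6,chest,Al,15.4519,ok
6,thigh,Al,14.1418,ok
6,liver,Al,0.03626,ok
1,chest,Cd,0.0304,ok
1,thigh,Cd,0.0293,ok
1,liver,Cd,0.000148,ok
2,chest,Cd,0.007906,ok
2,thigh,Cd,0.04969,ok
2,liver,Cd,0.0000828,anomaly
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
1,chest,Pb,0.363817,ok
1,thigh,Pb,0.152755,ok
1,liver,Pb,0.0000521,ok
2,chest,Pb,0.44499,ok
2,thigh,Pb,0.04715,ok
2,liver,Pb,0.00034,ok
3,chest,Pb,0.361417,ok
3,thigh,Pb,0.1120957,ok
3,liver,Pb,0.00033428,ok
4,chest,Pb,0.0365511,anomaly
4,thigh,Pb,0.1416021,ok
4,liver,Pb,0.0002353,ok
5,chest,Pb,0.4660304,ok
5,thigh,Pb,0.102778,ok
5,liver,Pb,0.0002617,ok
6,chest,Pb,0.783823,ok
6,thigh,Pb,0.0741187,ok
6,liver,Pb,0.0002375,ok
1,chest,Ba,0.050227,ok
1,thigh,Ba,0.040393,ok
1,liver,Ba,0.00002118,ok
2,chest,Ba,0.022814,ok
2,thigh,Ba,0.029445,anomaly
2,liver,Ba,0.00008916,ok
3,chest,Ba,0.0229031,ok
3,thigh,Ba,0.0546885,ok
3,liver,Ba,0.0000637,ok
4,chest,Ba,0.0203297,ok
4,thigh,Ba,0.0448463,ok
4,liver,Ba,0.0000776,ok
5,chest,Ba,0.025904,ok
5,thigh,Ba,0.028493,ok
5,liver,Ba,0.0000312,ok
6,chest,Ba,0.0159,ok
6,thigh,Ba,000.033487,ok
6,liver,Ba,0.0000901,ok
1,chest,Bi,6.866146,ok
1,thigh,Bi,0.012267,ok
1,liver,Bi,0.0000541,ok
2,chest,Bi,2.654157,ok
2,thigh,Bi,0.008373,ok
2,liver,Bi,0.0000507,ok
3,chest,Bi,1.699984,ok
3,thigh,Bi,0.013436,ok
3,liver,Bi,0.0000527,ok
4,chest,Bi,1.143059,ok
4,thigh,Bi,0.025898,ok
4,liver,Bi,0.00004532,anomaly
5,chest,Bi,1.4001019,ok
5,thigh,Bi,0.0103206,ok
5,liver,Bi,0.00000492,ok
6,chest,Bi,1.337788,ok
6,thigh,Bi,0.016357,ok
6,liver,Bi,0.00005024,ok
1,chest,Co,0.1035509,ok
1,thigh,Co,0.0734128,ok
1,liver,Co,0.0002142,ok
2,chest,Co,0.0978838,ok
2,thigh,Co,0.0263533,ok
2,liver,Co,0.0002523,ok
3,chest,Co,0.0960014,ok
3,thigh,Co,0.0734128,ok
3,liver,Co,0.00019047,ok
4,chest,Co,0.156237,ok
4,thigh,Co,0.069648,ok
4,liver,Co,0.000219,ok
5,chest,Co,00.073412,ok
5,thigh,Co,0.0621185,ok
5,liver,Co,0.0001333,ok
6,chest,Co,0.1261195,ok
6,thigh,Co,0.03953,ok
6,liver,Co,0.0001380,ok
1,chest,Ni,0.0064377,ok
1,thigh,Ni,0.0072001,ok
1,liver,Ni,0.0000155,ok
2,chest,Ni,0.0043483,ok
2,thigh,Ni,0.0040377,ok
2,liver,Ni,0.000008,ok
3,chest,Ni,0.0049977,ok
3,thigh,Ni,0.004433,ok
3,liver,Ni,00.0000123,ok
4,chest,Ni,0.0050824,ok
4,thigh,Ni,0.0040941,ok
4,liver,Ni,0.0000134,ok
5,chest,Ni,0.0051389,ok
5,thigh,Ni,0.0053365,ok
5,liver,Ni,0.0000124,ok
6,chest,Ni,0.00604244,ok
6,thigh,Ni,0.00460042,ok
6,liver,Ni,0.00001278,ok
1,chest,Cr,0.114637,ok
1,thigh,Cr,0.086589,ok
1,liver,Cr,0.0002247,ok
2,chest,Cr,0.4169473,ok
2,thigh,Cr,0.0335063,ok
2,liver,Cr,0.0000766,ok
3,chest,Cr,0.053271,ok
3,thigh,Cr,0.034071,ok
3,liver,Cr,0.000089,ok
4,chest,Cr,00.0500713,ok
4,thigh,Cr,0.0444241,ok
4,liver,Cr,0.0006771,ok
5,chest,Cr,0.0502595,ok
5,thigh,Cr,0.0320004,ok
5,liver,Cr,0.0000914,ok
6,chest,Cr,0.0557184,ok
6,thigh,Cr,0.0440477,ok
6,liver,Cr,0.0000957,ok
1,chest,Fe,0.0184217,ok
1,thigh,Fe,0.0144937,ok
1,liver,Fe,0.00007799,ok
2,chest,Fe,0.00703069,ok
2,thigh,Fe,0.00369726,ok
2,liver,Fe,0.00007874,ok
3,chest,Fe,0.0171657,ok
3,thigh,Fe,0.0124003,ok
3,liver,Fe,0.0000872,ok
4,chest,Fe,0.0061561,ok
4,thigh,Fe,0.0148116,ok
4,liver,Fe,0.0000982,ok
5,chest,Fe,0.00666766,ok
5,thigh,Fe,0.00492511,ok
5,liver,Fe,0.00003928,anomaly
6,chest,Fe,0.025496,ok
6,thigh,Fe,00.0086844,ok
6,liver,Fe,0.0000624,ok
1,chest,Cu,0.1076345,ok
1,thigh,Cu,0.0910319,ok
1,liver,Cu,0.0011737,ok
2,chest,Cu,0.084933,ok
2,thigh,Cu,00.0823353,ok
2,liver,Cu,0.0009202,ok
3,chest,Cu,0.11170048,ok
3,thigh,Cu,0.06844337,ok
3,liver,Cu,0.00099285,ok
4,chest,Cu,0.0840294,ok
4,thigh,Cu,0.16004002,ok
4,liver,Cu,0.001071142,ok
5,chest,Cu,0.081318857,ok
5,thigh,Cu,0.093968457,ok
5,liver,Cu,0.0008811428,ok
6,chest,Cu,0.083125942,ok
6,thigh,Cu,0.071154,ok
6,liver,Cu,0.00087742,ok
1,chest,Zn,0.0212031,ok
1,thigh,Zn,0.0325124,ok
1,liver,Zn,0.0001522,ok
2,chest,Zn,0.01662518,ok
2,thigh,Zn,0.02943102,ok
2,liver,Zn,0.00010929,ok
3,chest,Zn,0.0149893,ok
3,thigh,Zn,0.0285576,ok
3,liver,Zn,0.00011258,ok
4,chest,Zn,0.02605591,ok
4,thigh,Zn,0.03789421,ok
4,liver,Zn,0.00012078,ok
5,chest,Zn,0.028791,ok
5,thigh,Zn,00.04290322,ok
5,liver,Zn,0.00011852,ok
6,chest,Zn,0.01920969,ok
6,thigh,Zn,0.03643913,ok
6,liver,Zn,0.00012377,ok
1,chest,Se,0.037835,ok
1,thigh,Se,0.043257,ok
1,liver,Se,0.0002331,ok
2,chest,Se,0.0269933,ok
2,thigh,Se,0.021685,ok
2,liver,Se,00.0001791,ok
3,chest,Se,0.031624,ok
3,thigh,Se,0.026428,ok
3,liver,Se,0.000171,ok
4,chest,Se,0.03207577,ok
4,thigh,Se,0.04257945,ok
4,liver,Se,0.00020114,ok
5,chest,Se,0.03128517,ok
5,thigh,Se,0.02676745,ok
5,liver,Se,0.00018828,ok
6,chest,Se,0.03038162,ok
6,thigh,Se,0.02304034,ok
6,liver,Se,0.00017228,ok
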