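brand,tissue,metal,n,mean_ug_g,se_ug_g
1,chest,Al,20,11.535,0.160
2,chest,Al,20,8.610,0.116
3,chest,Al,20,12.361,0.221
4,chest,Al,20,21.985,0.329
5,chest,Al,20,16.357,0.356
6,chest,Al,20,10.945,0.218
1,thigh,Al,20,12.808,0.111
2,thigh,Al,20,5.729,0.074
3,thigh,Al,20,18.533,0.382
4,thigh,Al,20,12.101,0.208
5,thigh,Al,20,16.357,0.355
6,thigh,Al,20,10.017,0.234
1,liver,Al,20,5.873,0.074
2,liver,Al,20,9.635,0.126
3,liver,Al,20,13.014,0.271
4,liver,Al,20,14.005,0.276
5,liver,Al,20,10.935,0.285
6,liver,Al,20,10.154,0.162
1,chest,Cd,20,0.054,0.001
2,chest,Cd,20,0.014,0.001
3,chest,Cd,20,0.029,0.001
4,chest,Cd,20,0.031,0.001
5,chest,Cd,20,0.024,0.001
6,chest,Cd,20,0.036,0.001
1,thigh,Cd,20,0.052,0.001
2,thigh,Cd,20,0.088,0.001
3,thigh,Cd,20,0.019,0.001
4,thigh,Cd,20,0.025,0.001
5,thigh,Cd,20,0.015,0.001
6,thigh,Cd,20,0.024,0.001
1,liver,Cd,20,0.104,0.002
2,liver,Cd,20,0.037,0.001
3,liver,Cd,20,0.047,0.002
4,liver,Cd,20,0.041,0.003
5,liver,Cd,20,0.027,0.0002
6,liver,Cd,20,0.039,0.003
1,chest,Pb,20,2.577,0.071
2,chest,Pb,20,3.152,0.154
3,chest,Pb,20,2.560,0.104
4,chest,Pb,20,2.589,0.090
5,chest,Pb,20,3.301,0.122
6,chest,Pb,20,5.552,0.322
1,thigh,Pb,20,1.082,0.006
2,thigh,Pb,20,0.334,0.001
3,thigh,Pb,20,0.794,0.007
4,thigh,Pb,20,1.003,0.011
5,thigh,Pb,20,0.728,0.005
6,thigh,Pb,20,0.525,0.002
1,liver,Pb,20,0.146,0.001
2,liver,Pb,20,0.952,0.001
3,liver,Pb,20,0.936,0.003
4,liver,Pb,20,0.659,0.004
5,liver,Pb,20,0.733,0.004
6,liver,Pb,20,0.665,0.006
1,chest,Ba,20,6.226,0.110
2,chest,Ba,20,2.828,1.443
3,chest,Ba,20,2.839,0.043
4,chest,Ba,20,2.520,0.059
5,chest,Ba,20,3.211,0.050
6,chest,Ba,20,1.971,0.050
1,thigh,Ba,20,5.007,0.106
2,thigh,Ba,20,3.216,0.026
3,thigh,Ba,20,6.779,0.090
4,thigh,Ba,20,5.559,0.163
5,thigh,Ba,20,3.532,0.107
6,thigh,Ba,20,4.151,0.116
1,liver,Ba,20,1.038,0.018
2,liver,Ba,20,4.369,0.112
3,liver,Ba,20,3.122,0.105
4,liver,Ba,20,3.807,0.070
5,liver,Ba,20,1.529,0.013
6,liver,Ba,20,4.416,0.107
1,chest,Bi,20,3.526,0.234
2,chest,Bi,20,1.363,0.090
3,chest,Bi,20,0.873,0.057
4,chest,Bi,20,0.587,0.038
5,chest,Bi,20,0.719,0.046
6,chest,Bi,20,0.687,0.045
1,thigh,Bi,20,0.0063,0.0001
2,thigh,Bi,20,0.0043,0.0004
3,thigh,Bi,20,0.0069,0.0001
4,thigh,Bi,20,0.0133,0.0003
5,thigh,Bi,20,0.0053,0.0001
6,thigh,Bi,20,0.0084,0.0001
1,liver,Bi,20,0.011,0.0001
2,liver,Bi,20,0.0103,0.001
3,liver,Bi,20,0.0107,0.0001
4,liver,Bi,20,0.009,0.0001
5,liver,Bi,20,0.001,0.0001
6,liver,Bi,20,0.0102,0.0001
1,chest,Co,20,0.055,0.001
2,chest,Co,20,0.052,0.001
3,chest,Co,20,0.051,0.001
4,chest,Co,20,0.083,0.003
5,chest,Co,20,0.039,0.001
6,chest,Co,20,0.067,0.002
1,thigh,Co,20,0.039,0.001
2,thigh,Co,20,0.014,0.001
3,thigh,Co,20,0.039,0.001
4,thigh,Co,20,0.037,0.001
5,thigh,Co,20,0.033,0.001
6,thigh,Co,20,0.021,0.001
1,liver,Co,20,0.045,0.002
2,liver,Co,20,0.053,0.001
3,liver,Co,20,0.040,0.003
4,liver,Co,20,0.046,0.0001
5,liver,Co,20,0.028,0.002
6,liver,Co,20,0.029,0.001
1,chest,Ni,20,0.228,0.001
2,chest,Ni,20,0.154,0.001
3,chest,Ni,20,0.177,0.001
4,chest,Ni,20,0.180,0.001
5,chest,Ni,20,0.182,0.002
6,chest,Ni,20,0.214,0.002
1,thigh,Ni,20,0.255,0.004
2,thigh,Ni,20,0.143,0.002
3,thigh,Ni,20,0.157,0.001
4,thigh,Ni,20,0.145,0.001
5,thigh,Ni,20,0.189,0.001
6,thigh,Ni,20,0.163,0.001
1,liver,Ni,20,0.217,0.001
2,liver,Ni,20,0.112,0.001
3,liver,Ni,20,0.173,0.001
4,liver,Ni,20,0.188,0.003
5,liver,Ni,20,0.174,0.001
6,liver,Ni,20,0.179,0.001
1,chest,Cr,20,0.609,0.024
2,chest,Cr,20,2.215,0.002
3,chest,Cr,20,0.283,0.006
4,chest,Cr,20,0.266,0.005
5,chest,Cr,20,0.267,0.005
6,chest,Cr,20,0.296,0.006
1,thigh,Cr,20,0.460,0.016
2,thigh,Cr,20,0.178,0.002
3,thigh,Cr,20,0.181,0.001
4,thigh,Cr,20,0.236,0.001
5,thigh,Cr,20,0.170,0.001
6,thigh,Cr,20,0.234,0.001
1,liver,Cr,20,0.472,0.013
2,liver,Cr,20,0.161,0.001
3,liver,Cr,20,0.187,0.001
4,liver,Cr,20,1.422,0.088
5,liver,Cr,20,0.192,0.002
6,liver,Cr,20,0.201,0.001
1,chest,Fe,20,22.835,0.499
2,chest,Fe,20,8.715,0.238
3,chest,Fe,20,21.278,0.869
4,chest,Fe,20,7.631,0.308
5,chest,Fe,20,8.265,0.385
6,chest,Fe,20,31.604,0.883
1,thigh,Fe,20,17.966,0.191
2,thigh,Fe,20,4.583,0.036
3,thigh,Fe,20,15.371,0.636
4,thigh,Fe,20,18.360,0.784
5,thigh,Fe,20,6.105,0.078
6,thigh,Fe,20,10.765,0.189
1,liver,Fe,20,38.219,0.201
2,liver,Fe,20,38.585,0.668
3,liver,Fe,20,42.771,0.732
4,liver,Fe,20,48.142,0.804
5,liver,Fe,20,24.151,0.200
6,liver,Fe,20,30.618,0.367
1,chest,Cu,20,0.953,0.011
2,chest,Cu,20,0.752,0.012
3,chest,Cu,20,0.989,0.028
4,chest,Cu,20,0.744,0.020
5,chest,Cu,20,0.720,0.016
6,chest,Cu,20,0.736,0.020
1,thigh,Cu,20,0.806,0.003
2,thigh,Cu,20,0.729,0.004
3,thigh,Cu,20,0.606,0.002
4,thigh,Cu,20,1.417,0.048
5,thigh,Cu,20,0.832,0.007
6,thigh,Cu,20,0.630,0.003
1,liver,Cu,20,4.108,0.010
2,liver,Cu,20,3.221,0.024
3,liver,Cu,20,3.475,0.017
4,liver,Cu,20,3.749,0.025
5,liver,Cu,20,3.084,0.023
6,liver,Cu,20,3.071,0.032
1,chest,Zn,20,11.264,0.193
2,chest,Zn,20,8.832,0.059
3,chest,Zn,20,7.963,0.094
4,chest,Zn,20,13.842,0.478
5,chest,Zn,20,15.295,0.590
6,chest,Zn,20,10.205,0.125
1,thigh,Zn,20,17.272,0.161
2,thigh,Zn,20,15.635,0.135
3,thigh,Zn,20,15.171,0.072
4,thigh,Zn,20,20.131,0.117
5,thigh,Zn,20,22.792,0.100
6,thigh,Zn,20,19.358,0.155
1,liver,Zn,20,31.980,0.141
2,liver,Zn,20,22.952,0.084
3,liver,Zn,20,23.643,0.129
4,liver,Zn,20,25.364,0.087
5,liver,Zn,20,24.891,0.119
6,liver,Zn,20,25.992,0.227
1,chest,Se,20,0.335,0.004
2,chest,Se,20,0.239,0.001
3,chest,Se,20,0.280,0.002
4,chest,Se,20,0.284,0.002
5,chest,Se,20,0.277,0.001
6,chest,Se,20,0.269,0.003
1,thigh,Se,20,0.383,0.003
2,thigh,Se,20,0.192,0.002
3,thigh,Se,20,0.234,0.001
4,thigh,Se,20,0.377,0.007
5,thigh,Se,20,0.237,0.002
6,thigh,Se,20,0.204,0.002
1,liver,Se,20,0.816,0.003
2,liver,Se,20,0.627,0.003
3,liver,Se,20,0.601,0.002
4,liver,Se,20,0.704,0.003
5,liver,Se,20,0.659,0.001
6,liver,Se,20,0.603,0.006
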