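brand,tissue,metal,printed,status
1,chest,Cd,1.158e-8,ok
1,thigh,Cd,1.115e-8,ok
1,liver,Cd,5.6e-11,ok
2,chest,Cd,3.0e-9,ok
2,thigh,Cd,1.888e-8,ok
2,liver,Cd,1.0e-11,anomaly
3,chest,Cd,6.65e-9,anomaly
3,thigh,Cd,4.07e-9,ok
3,liver,Cd,2.55e-11,ok
4,chest,Cd,6.65e-9,ok
4,thigh,Cd,5.36e-9,ok
4,liver,Cd,2.2e-11,ok
5,chest,Cd,5.15e-9,ok
5,thigh,Cd,3.21e-9,ok
5,liver,Cd,1.46e-11,ok
6,chest,Cd,7.72e-9,ok
6,thigh,Cd,5.15e-9,ok
6,liver,Cd,2.1e-11,ok
1,chest,Pb,1.236e-8,ok
1,thigh,Pb,5.19e-9,ok
1,liver,Pb,1.77e-12,ok
2,chest,Pb,1.512e-8,ok
2,thigh,Pb,1.60e-9,ok
2,liver,Pb,1.156e-11,ok
3,chest,Pb,1.22e-8,ok
3,thigh,Pb,3.8e-9,ok
3,liver,Pb,1.136e-11,ok
4,chest,Pb,1.24e-8,ok
4,thigh,Pb,4.81e-9,ok
4,liver,Pb,8.002e-12,ok
5,chest,Pb,1.584e-8,ok
5,thigh,Pb,3.49e-9,ok
5,liver,Pb,8.90e-12,ok
6,chest,Pb,2.66e-8,ok
6,thigh,Pb,2.52e-9,ok
6,liver,Pb,8.07e-12,ok
1,chest,Co,2.174e-8,ok
1,thigh,Co,1.541e-8,ok
1,liver,Co,4.5e-11,ok
2,chest,Co,2.055e-8,ok
2,thigh,Co,5.53e-9,ok
2,liver,Co,5.3e-11,ok
3,chest,Co,2.016e-8,ok
3,thigh,Co,1.541e-8,ok
3,liver,Co,4.0e-11,ok
4,chest,Co,3.28e-8,ok
4,thigh,Co,1.46e-8,ok
4,liver,Co,4.6e-11,ok
5,chest,Co,1.542e-8,ok
5,thigh,Co,1.304e-8,ok
5,liver,Co,2.8e-11,ok
6,chest,Co,2.648e-8,ok
6,thigh,Co,8.30e-9,ok
6,liver,Co,2.9e-11,ok
1,chest,Ni,2.188e-7,ok
1,thigh,Ni,2.448e-7,ok
1,liver,Ni,5.27e-10,ok
2,chest,Ni,1.478e-7,ok
2,thigh,Ni,1.372e-7,ok
2,liver,Ni,2.72e-10,ok
3,chest,Ni,1.699e-7,ok
3,thigh,Ni,1.507e-7,ok
3,liver,Ni,4.20e-10,ok
4,chest,Ni,1.728e-7,ok
4,thigh,Ni,1.392e-7,ok
4,liver,Ni,4.56e-10,ok
5,chest,Ni,1.747e-7,ok
5,thigh,Ni,1.814e-7,ok
5,liver,Ni,4.22e-10,ok
6,chest,Ni,2.054e-7,ok
6,thigh,Ni,1.565e-7,ok
6,liver,Ni,4.34e-10,ok
1,chest,Cr,1.719e-7,ok
1,thigh,Cr,1.298e-7,ok
1,liver,Cr,3.371e-10,ok
2,chest,Cr,6.254e-7,ok
2,thigh,Cr,5.026e-8,ok
2,liver,Cr,1.15e-10,ok
3,chest,Cr,7.990e-8,ok
3,thigh,Cr,5.111e-8,ok
3,liver,Cr,1.33e-10,ok
4,chest,Cr,7.511e-8,ok
4,thigh,Cr,6.664e-8,ok
4,liver,Cr,1.015e-9,ok
5,chest,Cr,7.539e-7,anomaly
5,thigh,Cr,4.800e-8,ok
5,liver,Cr,1.37e-10,ok
6,chest,Cr,1.672e-7,anomaly
6,thigh,Cr,6.607e-8,ok
6,liver,Cr,1.43e-10,ok
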