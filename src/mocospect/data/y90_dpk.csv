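radius_mm,dose_gy_g_per_decay_per_mm3
0.0,4.223071e-11
0.1,3.958853e-11
0.2,3.382042e-11
0.3,2.719753e-11
0.4,2.120541e-11
0.5,1.636290e-11
0.6,1.264426e-11
0.7,9.841934e-12
0.8,7.735036e-12
0.9,6.141815e-12
1.0,4.925589e-12
1.1,3.987052e-12
1.2,3.254792e-12
1.3,2.677386e-12
1.4,2.217549e-12
1.5,1.847979e-12
1.6,1.548463e-12
1.7,1.303873e-12
1.8,1.102755e-12
1.9,9.363458e-13
2.0,7.978753e-13
2.1,6.820599e-13
2.2,5.847413e-13
2.3,5.026189e-13
2.4,4.330530e-13
2.5,3.739171e-13
2.6,3.234867e-13
2.7,2.803549e-13
2.8,2.433671e-13
2.9,2.115708e-13
3.0,1.841764e-13
3.1,1.605261e-13
3.2,1.400701e-13
3.3,1.223463e-13
3.4,1.069657e-13
3.5,9.359892e-14
3.6,8.196690e-14
3.7,7.183204e-14
3.8,6.299166e-14
3.9,5.527241e-14
4.0,4.852566e-14
4.1,4.262371e-14
4.2,3.745660e-14
4.3,3.292948e-14
4.4,2.896036e-14
4.5,2.547829e-14
4.6,2.242174e-14
4.7,1.973731e-14
4.8,1.737855e-14
4.9,1.530504e-14
5.0,1.348155e-14
5.1,1.187736e-14
5.2,1.046561e-14
5.3,9.222857e-15
5.4,8.128568e-15
5.5,7.164775e-15
5.6,6.315732e-15
5.7,5.567632e-15
5.8,4.908363e-15
5.9,4.327290e-15
6.0,3.815072e-15
6.1,3.363502e-15
6.2,2.965361e-15
6.3,2.614302e-15
6.4,2.304738e-15
6.5,2.031753e-15
6.6,1.791016e-15
6.7,1.578715e-15
6.8,1.391490e-15
6.9,1.226380e-15
7.0,1.080775e-15
7.1,9.523753e-16
7.2,8.391513e-16
7.3,7.393143e-16
7.4,6.512865e-16
7.5,5.736760e-16
7.6,5.052551e-16
7.7,4.449404e-16
7.8,3.917761e-16
7.9,3.449191e-16
8.0,3.036250e-16
8.1,2.672375e-16
8.2,2.351770e-16
8.3,2.069323e-16
8.4,1.820524e-16
8.5,1.601391e-16
8.6,1.408414e-16
8.7,1.238493e-16
8.8,1.088894e-16
8.9,9.572073e-17
9.0,8.413042e-17
9.1,7.393088e-17
9.2,6.495662e-17
9.3,5.706170e-17
9.4,5.011744e-17
9.5,4.401037e-17
9.6,3.864046e-17
9.7,3.391954e-17
9.8,2.976989e-17
9.9,2.612302e-17
10.0,2.291859e-17
10.1,2.010342e-17
10.2,1.763068e-17
10.3,1.545911e-17
10.4,1.355239e-17
10.5,1.187853e-17
10.6,1.040936e-17
10.7,9.120113e-18
10.8,7.988961e-18
10.9,6.996711e-18
11.0,6.126477e-18
11.1,5.363403e-18
11.2,4.694427e-18
11.3,4.108062e-18
11.4,3.594208e-18
11.5,3.143988e-18
11.6,2.749603e-18
11.7,2.404197e-18
11.8,2.101750e-18
11.9,1.836972e-18
12.0,1.605219e-18
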