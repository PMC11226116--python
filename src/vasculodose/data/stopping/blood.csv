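# synthetic electron stopping/range table, material blood
# Bethe collision stopping, Z/A=0.54999, I=75.2 eV, no density effect
energy_keV,stopping_MeV_cm2_g,csda_range_g_cm2
1,1.185612e+02,8.434465e-06
1.059637,1.142707e+02,8.946916e-06
1.122831,1.100893e+02,9.510438e-06
1.189794,1.060184e+02,1.013037e-05
1.26075,1.020588e+02,1.081264e-05
1.335938,9.821087e+01,1.156378e-05
1.415609,9.447462e+01,1.239105e-05
1.500032,9.084969e+01,1.330248e-05
1.58949,8.733540e+01,1.430698e-05
1.684283,8.393081e+01,1.541438e-05
1.784729,8.063473e+01,1.663561e-05
1.891166,7.744575e+01,1.798277e-05
2.00395,7.436227e+01,1.946926e-05
2.12346,7.138256e+01,2.110994e-05
2.250097,6.850471e+01,2.292127e-05
2.384287,6.572673e+01,2.492150e-05
2.526479,6.304651e+01,2.713087e-05
2.677152,6.046187e+01,2.957182e-05
2.83681,5.797057e+01,3.226920e-05
3.005989,5.557031e+01,3.525059e-05
3.185258,5.325876e+01,3.854659e-05
3.375218,5.103356e+01,4.219109e-05
3.576507,4.889234e+01,4.622170e-05
3.789801,4.683271e+01,5.068014e-05
4.015814,4.485231e+01,5.561265e-05
4.255306,4.294875e+01,6.107056e-05
4.509081,4.111969e+01,6.711076e-05
4.777991,3.936279e+01,7.379638e-05
5.062937,3.767576e+01,8.119743e-05
5.364877,3.605631e+01,8.939157e-05
5.684823,3.450221e+01,9.846494e-05
6.023851,3.301126e+01,1.085131e-04
6.383097,3.158129e+01,1.196420e-04
6.763768,3.021020e+01,1.319692e-04
7.16714,2.889589e+01,1.456251e-04
7.594569,2.763636e+01,1.607542e-04
8.047489,2.642963e+01,1.775168e-04
8.527419,2.527376e+01,1.960909e-04
9.035971,2.416689e+01,2.166734e-04
9.574852,2.310717e+01,2.394831e-04
10.14587,2.209284e+01,2.647621e-04
10.75094,2.112217e+01,2.927791e-04
11.3921,2.019349e+01,3.238318e-04
12.07149,1.930517e+01,3.582500e-04
12.7914,1.845563e+01,3.963994e-04
13.55425,1.764335e+01,4.386849e-04
14.36259,1.686686e+01,4.855550e-04
15.21913,1.612472e+01,5.375064e-04
16.12676,1.541556e+01,5.950891e-04
17.08852,1.473804e+01,6.589118e-04
18.10763,1.409088e+01,7.296482e-04
19.18752,1.347283e+01,8.080435e-04
20.33181,1.288270e+01,8.949221e-04
21.54435,1.231932e+01,9.911954e-04
22.82919,1.178160e+01,1.097871e-03
24.19066,1.126845e+01,1.216061e-03
25.63333,1.077883e+01,1.346996e-03
27.16203,1.031177e+01,1.492032e-03
28.7819,9.866302e+00,1.652668e-03
30.49838,9.441504e+00,1.830555e-03
32.31722,9.036496e+00,2.027515e-03
34.24453,8.650426e+00,2.245555e-03
36.28678,8.282481e+00,2.486886e-03
38.45082,7.931876e+00,2.753941e-03
40.74393,7.597860e+00,3.049395e-03
43.17379,7.279711e+00,3.376191e-03
45.74855,6.976736e+00,3.737562e-03
48.47687,6.688272e+00,4.137055e-03
51.3679,6.413682e+00,4.578561e-03
54.43134,6.152357e+00,5.066347e-03
57.67748,5.903710e+00,5.605083e-03
61.11721,5.667183e+00,6.199880e-03
64.76207,5.442240e+00,6.856325e-03
68.62431,5.228366e+00,7.580517e-03
72.71688,5.025071e+00,8.379113e-03
77.05351,4.831884e+00,9.259366e-03
81.64878,4.648356e+00,1.022917e-02
86.51809,4.474056e+00,1.129711e-02
91.67779,4.308573e+00,1.247251e-02
97.14521,4.151514e+00,1.376547e-02
102.9387,4.002503e+00,1.518696e-02
109.0777,3.861182e+00,1.674881e-02
115.5828,3.727206e+00,1.846383e-02
122.4758,3.600250e+00,2.034583e-02
129.7799,3.479999e+00,2.240966e-02
137.5197,3.366156e+00,2.467133e-02
145.721,3.258435e+00,2.714800e-02
154.4114,3.156565e+00,2.985809e-02
163.62,3.060285e+00,3.282129e-02
173.3779,2.969348e+00,3.605866e-02
183.7177,2.883517e+00,3.959266e-02
194.6741,2.802567e+00,4.344720e-02
206.2839,2.726283e+00,4.764773e-02
218.5862,2.654459e+00,5.222123e-02
231.622,2.586900e+00,5.719630e-02
245.4353,2.523418e+00,6.260318e-02
260.0724,2.463835e+00,6.847382e-02
275.5825,2.407980e+00,7.484190e-02
292.0175,2.355691e+00,8.174287e-02
309.4326,2.306812e+00,8.921398e-02
327.8863,2.261194e+00,9.729434e-02
347.4405,2.218696e+00,1.060249e-01
368.161,2.179181e+00,1.154486e-01
390.1171,2.142519e+00,1.256102e-01
413.3826,2.108586e+00,1.365565e-01
438.0356,2.077261e+00,1.483364e-01
464.1589,2.048432e+00,1.610007e-01
491.8401,2.021986e+00,1.746025e-01
521.1721,1.997819e+00,1.891967e-01
552.2534,1.975830e+00,2.048409e-01
585.1883,1.955920e+00,2.215946e-01
620.0873,1.937995e+00,2.395199e-01
657.0676,1.921965e+00,2.586812e-01
696.2533,1.907743e+00,2.791456e-01
737.776,1.895243e+00,3.009827e-01
781.775,1.884385e+00,3.242651e-01
828.3979,1.875091e+00,3.490681e-01
877.8013,1.867283e+00,3.754704e-01
930.151,1.860890e+00,4.035538e-01
985.6227,1.855840e+00,4.334035e-01
1044.403,1.852065e+00,4.651087e-01
1106.688,1.849499e+00,4.987623e-01
1172.688,1.848079e+00,5.344612e-01
1242.624,1.847742e+00,5.723072e-01
1316.73,1.848430e+00,6.124064e-01
1395.257,1.850085e+00,6.548700e-01
1478.466,1.852653e+00,6.998148e-01
1566.638,1.856080e+00,7.473630e-01
1660.068,1.860317e+00,7.976430e-01
1759.07,1.865313e+00,8.507895e-01
1863.976,1.871024e+00,9.069441e-01
1975.138,1.877403e+00,9.662558e-01
2092.93,1.884409e+00,1.028881e+00
2217.747,1.892001e+00,1.094985e+00
2350.007,1.900139e+00,1.164740e+00
2490.155,1.908789e+00,1.238330e+00
2638.661,1.917913e+00,1.315946e+00
2796.024,1.927480e+00,1.397791e+00
2962.771,1.937458e+00,1.484079e+00
3139.463,1.947817e+00,1.575034e+00
3326.692,1.958531e+00,1.670894e+00
3525.087,1.969571e+00,1.771908e+00
3735.313,1.980915e+00,1.878339e+00
3958.077,1.992539e+00,1.990466e+00
4194.126,2.004420e+00,2.108582e+00
4444.253,2.016540e+00,2.232994e+00
4709.296,2.028879e+00,2.364029e+00
4990.145,2.041420e+00,2.502030e+00
5287.744,2.054147e+00,2.647358e+00
5603.091,2.067043e+00,2.800397e+00
5937.244,2.080096e+00,2.961547e+00
6291.325,2.093292e+00,3.131234e+00
6666.523,2.106619e+00,3.309905e+00
7064.096,2.120066e+00,3.498032e+00
7485.38,2.133623e+00,3.696113e+00
7931.787,2.147280e+00,3.904673e+00
8404.818,2.161028e+00,4.124265e+00
8906.058,2.174861e+00,4.355473e+00
9437.191,2.188769e+00,4.598912e+00
10000,2.202747e+00,4.855231e+00
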