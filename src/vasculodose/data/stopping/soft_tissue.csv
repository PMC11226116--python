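# synthetic electron stopping/range table, material soft_tissue
# Bethe collision stopping, Z/A=0.54996, I=75.0 eV, no density effect
energy_keV,stopping_MeV_cm2_g,csda_range_g_cm2
1,1.186700e+02,8.426727e-06
1.059637,1.143733e+02,8.938714e-06
1.122831,1.101861e+02,9.501735e-06
1.189794,1.061096e+02,1.012113e-05
1.26075,1.021448e+02,1.080282e-05
1.335938,9.829194e+01,1.155333e-05
1.415609,9.455105e+01,1.237993e-05
1.500032,9.092174e+01,1.329063e-05
1.58949,8.740333e+01,1.429434e-05
1.684283,8.399486e+01,1.540089e-05
1.784729,8.069511e+01,1.662120e-05
1.891166,7.750268e+01,1.796736e-05
2.00395,7.441595e+01,1.945276e-05
2.12346,7.143317e+01,2.109227e-05
2.250097,6.855243e+01,2.290233e-05
2.384287,6.577172e+01,2.490118e-05
2.526479,6.308894e+01,2.710906e-05
2.677152,6.050188e+01,2.954837e-05
2.83681,5.800829e+01,3.224398e-05
3.005989,5.560588e+01,3.522346e-05
3.185258,5.329231e+01,3.851736e-05
3.375218,5.106520e+01,4.215958e-05
3.576507,4.892217e+01,4.618772e-05
3.789801,4.686085e+01,5.064346e-05
4.015814,4.487884e+01,5.557304e-05
4.255306,4.297378e+01,6.102774e-05
4.509081,4.114330e+01,6.706445e-05
4.777991,3.938506e+01,7.374626e-05
5.062937,3.769677e+01,8.114315e-05
5.364877,3.607613e+01,8.933276e-05
5.684823,3.452091e+01,9.840119e-05
6.023851,3.302890e+01,1.084439e-04
6.383097,3.159793e+01,1.195669e-04
6.763768,3.022590e+01,1.318877e-04
7.16714,2.891071e+01,1.455365e-04
7.594569,2.765035e+01,1.606579e-04
8.047489,2.644282e+01,1.774122e-04
8.527419,2.528622e+01,1.959770e-04
9.035971,2.417864e+01,2.165495e-04
9.574852,2.311827e+01,2.393481e-04
10.14587,2.210332e+01,2.646150e-04
10.75094,2.113206e+01,2.926189e-04
11.3921,2.020283e+01,3.236571e-04
12.07149,1.931399e+01,3.580596e-04
12.7914,1.846396e+01,3.961916e-04
13.55425,1.765122e+01,4.384582e-04
14.36259,1.687429e+01,4.853075e-04
15.21913,1.613174e+01,5.372361e-04
16.12676,1.542219e+01,5.947939e-04
17.08852,1.474431e+01,6.585893e-04
18.10763,1.409680e+01,7.292958e-04
19.18752,1.347843e+01,8.076584e-04
20.33181,1.288799e+01,8.945011e-04
21.54435,1.232433e+01,9.907350e-04
22.82919,1.178634e+01,1.097367e-03
24.19066,1.127293e+01,1.215510e-03
25.63333,1.078308e+01,1.346393e-03
27.16203,1.031579e+01,1.491373e-03
28.7819,9.870104e+00,1.651946e-03
30.49838,9.445105e+00,1.829765e-03
32.31722,9.039906e+00,2.026651e-03
34.24453,8.653657e+00,2.244609e-03
36.28678,8.285543e+00,2.485850e-03
38.45082,7.934779e+00,2.752806e-03
40.74393,7.600613e+00,3.048153e-03
43.17379,7.282323e+00,3.374832e-03
45.74855,6.979215e+00,3.736074e-03
48.47687,6.690625e+00,4.135425e-03
51.3679,6.415917e+00,4.576777e-03
54.43134,6.154480e+00,5.064394e-03
57.67748,5.905728e+00,5.602945e-03
61.11721,5.669102e+00,6.197540e-03
64.76207,5.444065e+00,6.853763e-03
68.62431,5.230104e+00,7.577714e-03
72.71688,5.026725e+00,8.376046e-03
77.05351,4.833460e+00,9.256010e-03
81.64878,4.649858e+00,1.022550e-02
86.51809,4.475489e+00,1.129309e-02
91.67779,4.309941e+00,1.246812e-02
97.14521,4.152820e+00,1.376067e-02
102.9387,4.003752e+00,1.518171e-02
109.0777,3.862375e+00,1.674308e-02
115.5828,3.728349e+00,1.845758e-02
122.4758,3.601344e+00,2.033900e-02
129.7799,3.481047e+00,2.240221e-02
137.5197,3.367161e+00,2.466320e-02
145.721,3.259400e+00,2.713913e-02
154.4114,3.157491e+00,2.984842e-02
163.62,3.061175e+00,3.281075e-02
173.3779,2.970204e+00,3.604719e-02
183.7177,2.884342e+00,3.958017e-02
194.6741,2.803362e+00,4.343362e-02
206.2839,2.727050e+00,4.763297e-02
218.5862,2.655199e+00,5.220518e-02
231.622,2.587615e+00,5.717887e-02
245.4353,2.524110e+00,6.258426e-02
260.0724,2.464504e+00,6.845330e-02
275.5825,2.408629e+00,7.481966e-02
292.0175,2.356320e+00,8.171878e-02
309.4326,2.307423e+00,8.918791e-02
327.8863,2.261788e+00,9.726613e-02
347.4405,2.219273e+00,1.059944e-01
368.161,2.179743e+00,1.154157e-01
390.1171,2.143067e+00,1.255747e-01
413.3826,2.109120e+00,1.365182e-01
438.0356,2.077783e+00,1.482951e-01
464.1589,2.048941e+00,1.609563e-01
491.8401,2.022485e+00,1.745546e-01
521.1721,1.998308e+00,1.891453e-01
552.2534,1.976309e+00,2.047857e-01
585.1883,1.956389e+00,2.215354e-01
620.0873,1.938456e+00,2.394564e-01
657.0676,1.922418e+00,2.586132e-01
696.2533,1.908188e+00,2.790727e-01
737.776,1.895681e+00,3.009048e-01
781.775,1.884817e+00,3.241818e-01
828.3979,1.875516e+00,3.489792e-01
877.8013,1.867703e+00,3.753755e-01
930.151,1.861304e+00,4.034526e-01
985.6227,1.856250e+00,4.332958e-01
1044.403,1.852470e+00,4.649940e-01
1106.688,1.849899e+00,4.986402e-01
1172.688,1.848475e+00,5.343315e-01
1242.624,1.848134e+00,5.721694e-01
1316.73,1.848818e+00,6.122601e-01
1395.257,1.850470e+00,6.547149e-01
1478.466,1.853035e+00,6.996503e-01
1566.638,1.856459e+00,7.471888e-01
1660.068,1.860693e+00,7.974585e-01
1759.07,1.865687e+00,8.505944e-01
1863.976,1.871395e+00,9.067378e-01
1975.138,1.877772e+00,9.660378e-01
2092.93,1.884775e+00,1.028651e+00
2217.747,1.892365e+00,1.094742e+00
2350.007,1.900502e+00,1.164484e+00
2490.155,1.909149e+00,1.238059e+00
2638.661,1.918272e+00,1.315661e+00
2796.024,1.927837e+00,1.397491e+00
2962.771,1.937813e+00,1.483763e+00
3139.463,1.948171e+00,1.574701e+00
3326.692,1.958883e+00,1.670544e+00
3525.087,1.969922e+00,1.771539e+00
3735.313,1.981265e+00,1.877952e+00
3958.077,1.992887e+00,1.990060e+00
4194.126,2.004768e+00,2.108154e+00
4444.253,2.016886e+00,2.232545e+00
4709.296,2.029224e+00,2.363558e+00
4990.145,2.041764e+00,2.501535e+00
5287.744,2.054489e+00,2.646840e+00
5603.091,2.067385e+00,2.799852e+00
5937.244,2.080437e+00,2.960976e+00
6291.325,2.093631e+00,3.130636e+00
6666.523,2.106957e+00,3.309278e+00
7064.096,2.120404e+00,3.497375e+00
7485.38,2.133959e+00,3.695425e+00
7931.787,2.147616e+00,3.903952e+00
8404.818,2.161363e+00,4.123510e+00
8906.058,2.175195e+00,4.354682e+00
9437.191,2.189102e+00,4.598084e+00
10000,2.203079e+00,4.854364e+00
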