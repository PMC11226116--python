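# synthetic electron stopping/range table, material gold
# Bethe collision stopping, Z/A=0.40108, I=790.0 eV, no density effect
energy_keV,stopping_MeV_cm2_g,csda_range_g_cm2
1,2.017852e+01,4.955766e-05
1.059637,1.926475e+01,5.258323e-05
1.122831,1.839237e+01,5.594132e-05
1.189794,1.755949e+01,5.966844e-05
1.26075,1.676433e+01,6.380517e-05
1.335938,1.600517e+01,6.839652e-05
1.415609,1.639834e+01,7.331472e-05
1.500032,1.669721e+01,7.841691e-05
1.58949,1.691117e+01,8.374067e-05
1.684283,1.704886e+01,8.932338e-05
1.784729,1.711818e+01,9.520311e-05
1.891166,1.712643e+01,1.014194e-04
2.00395,1.708026e+01,1.080136e-04
2.12346,1.698581e+01,1.150301e-04
2.250097,1.684866e+01,1.225159e-04
2.384287,1.667394e+01,1.305220e-04
2.526479,1.646633e+01,1.391036e-04
2.677152,1.623011e+01,1.483205e-04
2.83681,1.596916e+01,1.582381e-04
3.005989,1.568704e+01,1.689275e-04
3.185258,1.538697e+01,1.804667e-04
3.375218,1.507189e+01,1.929413e-04
3.576507,1.474445e+01,2.064449e-04
3.789801,1.440706e+01,2.210802e-04
4.015814,1.406190e+01,2.369605e-04
4.255306,1.371092e+01,2.542097e-04
4.509081,1.335589e+01,2.729647e-04
4.777991,1.299840e+01,2.933757e-04
5.062937,1.263987e+01,3.156083e-04
5.364877,1.228155e+01,3.398446e-04
5.684823,1.192459e+01,3.662855e-04
6.023851,1.156998e+01,3.951522e-04
6.383097,1.121861e+01,4.266883e-04
6.763768,1.087125e+01,4.611624e-04
7.16714,1.052858e+01,4.988708e-04
7.594569,1.019120e+01,5.401398e-04
8.047489,9.859604e+00,5.853293e-04
8.527419,9.534236e+00,6.348363e-04
9.035971,9.215461e+00,6.890985e-04
9.574852,8.903588e+00,7.485983e-04
10.14587,8.598867e+00,8.138682e-04
10.75094,8.301499e+00,8.854950e-04
11.3921,8.011641e+00,9.641260e-04
12.07149,7.729408e+00,1.050475e-03
12.7914,7.454879e+00,1.145329e-03
13.55425,7.188099e+00,1.249556e-03
14.36259,6.929085e+00,1.364113e-03
15.21913,6.677828e+00,1.490055e-03
16.12676,6.434293e+00,1.628544e-03
17.08852,6.198428e+00,1.780861e-03
18.10763,5.970160e+00,1.948419e-03
19.18752,5.749400e+00,2.132773e-03
20.33181,5.536048e+00,2.335636e-03
21.54435,5.329988e+00,2.558895e-03
22.82919,5.131097e+00,2.804627e-03
24.19066,4.939240e+00,3.075118e-03
25.63333,4.754278e+00,3.372882e-03
27.16203,4.576062e+00,3.700686e-03
28.7819,4.404441e+00,4.061570e-03
30.49838,4.239260e+00,4.458877e-03
32.31722,4.080358e+00,4.896278e-03
34.24453,3.927574e+00,5.377804e-03
36.28678,3.780747e+00,5.907878e-03
38.45082,3.639712e+00,6.491354e-03
40.74393,3.504306e+00,7.133549e-03
43.17379,3.374366e+00,7.840291e-03
45.74855,3.249730e+00,8.617961e-03
48.47687,3.130237e+00,9.473538e-03
51.3679,3.015728e+00,1.041465e-02
54.43134,2.906046e+00,1.144965e-02
57.67748,2.801037e+00,1.258761e-02
61.11721,2.700547e+00,1.383848e-02
64.76207,2.604430e+00,1.521306e-02
68.62431,2.512537e+00,1.672313e-02
72.71688,2.424726e+00,1.838148e-02
77.05351,2.340858e+00,2.020203e-02
81.64878,2.260796e+00,2.219985e-02
86.51809,2.184407e+00,2.439132e-02
91.67779,2.111562e+00,2.679412e-02
97.14521,2.042135e+00,2.942741e-02
102.9387,1.976005e+00,3.231186e-02
109.0777,1.913052e+00,3.546974e-02
115.5828,1.853162e+00,3.892506e-02
122.4758,1.796224e+00,4.270362e-02
129.7799,1.742130e+00,4.683313e-02
137.5197,1.690775e+00,5.134328e-02
145.721,1.642060e+00,5.626585e-02
154.4114,1.595886e+00,6.163479e-02
163.62,1.552160e+00,6.748632e-02
173.3779,1.510791e+00,7.385902e-02
183.7177,1.471692e+00,8.079389e-02
194.6741,1.434779e+00,8.833444e-02
206.2839,1.399970e+00,9.652676e-02
218.5862,1.367186e+00,1.054196e-01
231.622,1.336354e+00,1.150644e-01
245.4353,1.307399e+00,1.255154e-01
260.0724,1.280252e+00,1.368297e-01
275.5825,1.254846e+00,1.490672e-01
292.0175,1.231115e+00,1.622906e-01
309.4326,1.208996e+00,1.765659e-01
327.8863,1.188431e+00,1.919616e-01
347.4405,1.169359e+00,2.085496e-01
368.161,1.151726e+00,2.264047e-01
390.1171,1.135476e+00,2.456048e-01
413.3826,1.120557e+00,2.662309e-01
438.0356,1.106920e+00,2.883671e-01
464.1589,1.094513e+00,3.121008e-01
491.8401,1.083291e+00,3.375226e-01
521.1721,1.073207e+00,3.647266e-01
552.2534,1.064216e+00,3.938101e-01
585.1883,1.056276e+00,4.248740e-01
620.0873,1.049343e+00,4.580228e-01
657.0676,1.043378e+00,4.933649e-01
696.2533,1.038340e+00,5.310127e-01
737.776,1.034191e+00,5.710823e-01
781.775,1.030893e+00,6.136947e-01
828.3979,1.028409e+00,6.589751e-01
877.8013,1.026703e+00,7.070537e-01
930.151,1.025741e+00,7.580658e-01
985.6227,1.025489e+00,8.121521e-01
1044.403,1.025914e+00,8.694591e-01
1106.688,1.026983e+00,9.301395e-01
1172.688,1.028665e+00,9.943528e-01
1242.624,1.030930e+00,1.062265e+00
1316.73,1.033748e+00,1.134051e+00
1395.257,1.037090e+00,1.209891e+00
1478.466,1.040929e+00,1.289976e+00
1566.638,1.045238e+00,1.374507e+00
1660.068,1.049990e+00,1.463691e+00
1759.07,1.055160e+00,1.557748e+00
1863.976,1.060725e+00,1.656909e+00
1975.138,1.066661e+00,1.761416e+00
2092.93,1.072945e+00,1.871523e+00
2217.747,1.079556e+00,1.987498e+00
2350.007,1.086473e+00,2.109622e+00
2490.155,1.093677e+00,2.238190e+00
2638.661,1.101149e+00,2.373516e+00
2796.024,1.108871e+00,2.515926e+00
2962.771,1.116826e+00,2.665766e+00
3139.463,1.124998e+00,2.823400e+00
3326.692,1.133372e+00,2.989211e+00
3525.087,1.141933e+00,3.163603e+00
3735.313,1.150668e+00,3.347002e+00
3958.077,1.159563e+00,3.539855e+00
4194.126,1.168608e+00,3.742634e+00
4444.253,1.177790e+00,3.955838e+00
4709.296,1.187100e+00,4.179989e+00
4990.145,1.196526e+00,4.415642e+00
5287.744,1.206061e+00,4.663378e+00
5603.091,1.215696e+00,4.923810e+00
5937.244,1.225421e+00,5.197585e+00
6291.325,1.235231e+00,5.485384e+00
6666.523,1.245118e+00,5.787925e+00
7064.096,1.255076e+00,6.105964e+00
7485.38,1.265099e+00,6.440299e+00
7931.787,1.275181e+00,6.791768e+00
8404.818,1.285317e+00,7.161256e+00
8906.058,1.295504e+00,7.549697e+00
9437.191,1.305735e+00,7.958073e+00
10000,1.316009e+00,8.387419e+00
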