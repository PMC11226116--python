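# synthetic photon mass attenuation table, element H (Z=1, A=1.008)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,0.000000e+00,3.958932e-01,3.567202e-01,0.000000e+00
1.109031,0.000000e+00,3.957254e-01,3.483886e-01,0.000000e+00
1.229951,0.000000e+00,3.955396e-01,3.386066e-01,0.000000e+00
1.364054,0.000000e+00,3.953337e-01,3.272318e-01,0.000000e+00
1.512778,0.000000e+00,3.951057e-01,3.141543e-01,0.000000e+00
1.677719,0.000000e+00,3.948532e-01,2.993177e-01,0.000000e+00
1.860642,0.000000e+00,3.945737e-01,2.827418e-01,0.000000e+00
2.063511,0.000000e+00,3.942644e-01,2.645442e-01,0.000000e+00
2.288498,0.000000e+00,3.939220e-01,2.449558e-01,0.000000e+00
2.538016,0.000000e+00,3.935432e-01,2.243229e-01,0.000000e+00
2.814739,0.000000e+00,3.931243e-01,2.030926e-01,0.000000e+00
3.121634,0.000000e+00,3.926610e-01,1.817786e-01,0.000000e+00
3.46199,0.000000e+00,3.921489e-01,1.609108e-01,0.000000e+00
3.839456,0.000000e+00,3.915829e-01,1.409781e-01,0.000000e+00
4.258077,0.000000e+00,3.909578e-01,1.223784e-01,0.000000e+00
4.722341,0.000000e+00,3.902675e-01,1.053852e-01,0.000000e+00
5.237224,0.000000e+00,3.895057e-01,9.013978e-02,0.000000e+00
5.808245,0.000000e+00,3.886654e-01,7.666505e-02,0.000000e+00
6.441526,0.000000e+00,3.877390e-01,6.489432e-02,0.000000e+00
7.143854,0.000000e+00,3.867183e-01,5.470412e-02,0.000000e+00
7.922758,0.000000e+00,3.855945e-01,4.594298e-02,0.000000e+00
8.786587,0.000000e+00,3.843582e-01,3.845218e-02,0.000000e+00
9.744601,0.000000e+00,3.829993e-01,3.207811e-02,0.000000e+00
10.80707,0.000000e+00,3.815069e-01,2.667824e-02,0.000000e+00
11.98538,0.000000e+00,3.798696e-01,2.212314e-02,0.000000e+00
13.29216,0.000000e+00,3.780753e-01,1.829658e-02,0.000000e+00
14.74142,0.000000e+00,3.761114e-01,1.509490e-02,0.000000e+00
16.3487,0.000000e+00,3.739648e-01,1.242620e-02,0.000000e+00
18.13122,0.000000e+00,3.716217e-01,1.020957e-02,0.000000e+00
20.10809,0.000000e+00,3.690685e-01,8.374287e-03,0.000000e+00
22.3005,0.000000e+00,3.662909e-01,6.859070e-03,0.000000e+00
24.73195,0.000000e+00,3.632750e-01,5.611226e-03,0.000000e+00
27.42851,0.000000e+00,3.600072e-01,4.585809e-03,0.000000e+00
30.41908,0.000000e+00,3.564741e-01,3.744762e-03,0.000000e+00
33.73571,0.000000e+00,3.526634e-01,3.056064e-03,0.000000e+00
37.41396,0.000000e+00,3.485639e-01,2.492927e-03,0.000000e+00
41.49326,0.000000e+00,3.441660e-01,2.033055e-03,0.000000e+00
46.01732,0.000000e+00,3.394618e-01,1.657968e-03,0.000000e+00
51.03465,0.000000e+00,3.344461e-01,1.352408e-03,0.000000e+00
56.59903,0.000000e+00,3.291161e-01,1.103819e-03,0.000000e+00
62.7701,0.000000e+00,3.234723e-01,9.018973e-04,0.000000e+00
69.61401,0.000000e+00,3.175186e-01,7.382121e-04,0.000000e+00
77.20412,0.000000e+00,3.112626e-01,6.058824e-04,0.000000e+00
85.62178,0.000000e+00,3.047158e-01,4.993040e-04,0.000000e+00
94.95724,0.000000e+00,2.978935e-01,4.139188e-04,0.000000e+00
105.3106,0.000000e+00,2.908151e-01,3.460177e-04,0.000000e+00
116.7927,0.000000e+00,2.835036e-01,2.925709e-04,0.000000e+00
129.5268,0.000000e+00,2.759849e-01,2.510791e-04,0.000000e+00
143.6493,0.000000e+00,2.682882e-01,2.194461e-04,0.000000e+00
159.3115,0.000000e+00,2.604443e-01,1.958744e-04,0.000000e+00
176.6815,0.000000e+00,2.524856e-01,1.787902e-04,0.000000e+00
195.9453,0.000000e+00,2.444449e-01,1.668014e-04,0.000000e+00
217.3095,0.000000e+00,2.363549e-01,1.586863e-04,0.000000e+00
241.003,0.000000e+00,2.282470e-01,1.534020e-04,0.000000e+00
267.2799,0.000000e+00,2.201509e-01,1.500962e-04,0.000000e+00
296.4218,0.000000e+00,2.120939e-01,1.481095e-04,0.000000e+00
328.741,0.000000e+00,2.041005e-01,1.469611e-04,0.000000e+00
364.5841,0.000000e+00,1.961923e-01,1.463212e-04,0.000000e+00
404.3352,0.000000e+00,1.883877e-01,1.459767e-04,0.000000e+00
448.4204,0.000000e+00,1.807019e-01,1.457968e-04,0.000000e+00
497.3123,0.000000e+00,1.731476e-01,1.457053e-04,0.000000e+00
551.5349,0.000000e+00,1.657349e-01,1.456600e-04,0.000000e+00
611.6695,0.000000e+00,1.584719e-01,1.456380e-04,0.000000e+00
678.3607,0.000000e+00,1.513649e-01,1.456275e-04,0.000000e+00
752.3233,0.000000e+00,1.444191e-01,1.456225e-04,0.000000e+00
834.3501,0.000000e+00,1.376388e-01,1.456202e-04,0.000000e+00
925.3204,0.000000e+00,1.310279e-01,1.456192e-04,0.000000e+00
1026.209,0.000000e+00,1.245897e-01,1.456187e-04,0.000000e+00
1138.098,0.000000e+00,1.183276e-01,1.456185e-04,0.000000e+00
1262.187,0.000000e+00,1.122447e-01,1.456184e-04,0.000000e+00
1399.805,0.000000e+00,1.063442e-01,1.456183e-04,0.000000e+00
1552.427,0.000000e+00,1.006292e-01,1.456183e-04,0.000000e+00
1721.69,0.000000e+00,9.510261e-02,1.456183e-04,0.000000e+00
1909.409,0.000000e+00,8.976716e-02,1.456183e-04,0.000000e+00
2117.594,0.000000e+00,8.462517e-02,1.456183e-04,0.000000e+00
2348.478,0.000000e+00,7.967854e-02,1.456183e-04,0.000000e+00
2604.536,0.000000e+00,7.492861e-02,1.456183e-04,0.000000e+00
2888.512,0.000000e+00,7.037610e-02,1.456183e-04,0.000000e+00
3203.45,0.000000e+00,6.602105e-02,1.456183e-04,0.000000e+00
3552.727,0.000000e+00,6.186279e-02,1.456183e-04,3.986391e-05
3940.085,0.000000e+00,5.789990e-02,1.456183e-04,1.513243e-04
4369.678,0.000000e+00,5.413023e-02,1.456183e-04,2.627847e-04
4846.11,0.000000e+00,5.055094e-02,1.456183e-04,3.742450e-04
5374.488,0.000000e+00,4.715852e-02,1.456183e-04,4.857054e-04
5960.475,0.000000e+00,4.394883e-02,1.456183e-04,5.971658e-04
6610.354,0.000000e+00,4.091720e-02,1.456183e-04,7.086261e-04
7331.09,0.000000e+00,3.805847e-02,1.456183e-04,8.200865e-04
8130.408,0.000000e+00,3.536705e-02,1.456183e-04,9.315469e-04
9016.878,0.000000e+00,3.283704e-02,1.456183e-04,1.043007e-03
10000,0.000000e+00,3.046224e-02,1.456183e-04,1.154468e-03
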