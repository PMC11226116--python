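# synthetic photon mass attenuation table, element C (Z=6, A=12.011)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,2.072525e+03,1.993475e-01,1.160985e+00,0.000000e+00
1.109031,1.551784e+03,1.992630e-01,1.152164e+00,0.000000e+00
1.229951,1.157205e+03,1.991694e-01,1.141476e+00,0.000000e+00
1.364054,8.607806e+02,1.990657e-01,1.128568e+00,0.000000e+00
1.512778,6.389930e+02,1.989509e-01,1.113041e+00,0.000000e+00
1.677719,4.733915e+02,1.988238e-01,1.094455e+00,0.000000e+00
1.860642,3.499976e+02,1.986830e-01,1.072339e+00,0.000000e+00
2.063511,2.582435e+02,1.985273e-01,1.046206e+00,0.000000e+00
2.288498,1.901573e+02,1.983549e-01,1.015587e+00,0.000000e+00
2.538016,1.397383e+02,1.981641e-01,9.800692e-01,0.000000e+00
2.814739,1.024794e+02,1.979532e-01,9.393515e-01,0.000000e+00
3.121634,7.497590e+01,1.977199e-01,8.933098e-01,0.000000e+00
3.46199,5.472402e+01,1.974620e-01,8.420663e-01,0.000000e+00
3.839456,3.987463e+01,1.971771e-01,7.860520e-01,0.000000e+00
4.258077,2.900532e+01,1.968623e-01,7.260447e-01,0.000000e+00
4.722341,2.106301e+01,1.965147e-01,6.631667e-01,0.000000e+00
5.237224,1.526951e+01,1.961311e-01,5.988260e-01,0.000000e+00
5.808245,1.104171e+01,1.957079e-01,5.346002e-01,0.000000e+00
6.441526,7.973097e+00,1.952415e-01,4.720772e-01,0.000000e+00
7.143854,5.750235e+00,1.947275e-01,4.126836e-01,0.000000e+00
7.922758,4.142017e+00,1.941617e-01,3.575413e-01,0.000000e+00
8.786587,2.979927e+00,1.935391e-01,3.073851e-01,0.000000e+00
9.744601,2.136003e+00,1.928549e-01,2.625539e-01,0.000000e+00
10.80707,1.529578e+00,1.921034e-01,2.230467e-01,0.000000e+00
11.98538,1.094668e+00,1.912789e-01,1.886139e-01,0.000000e+00
13.29216,7.829505e-01,1.903754e-01,1.588564e-01,0.000000e+00
14.74142,5.596639e-01,1.893866e-01,1.333069e-01,0.000000e+00
16.3487,3.998171e-01,1.883056e-01,1.114870e-01,0.000000e+00
18.13122,2.854543e-01,1.871258e-01,9.293927e-02,0.000000e+00
20.10809,2.036821e-01,1.858401e-01,7.724178e-02,0.000000e+00
22.3005,1.452480e-01,1.844415e-01,6.401275e-02,0.000000e+00
24.73195,1.035163e-01,1.829229e-01,5.290991e-02,0.000000e+00
27.42851,7.365520e-02,1.812774e-01,4.362844e-02,0.000000e+00
30.41908,5.224952e-02,1.794984e-01,3.589847e-02,0.000000e+00
33.73571,3.707100e-02,1.775796e-01,2.948280e-02,0.000000e+00
37.41396,2.630626e-02,1.755153e-01,2.417451e-02,0.000000e+00
41.49326,1.867053e-02,1.733008e-01,1.979460e-02,0.000000e+00
46.01732,1.325337e-02,1.709321e-01,1.618945e-02,0.000000e+00
51.03465,9.409527e-03,1.684064e-01,1.322827e-02,0.000000e+00
56.59903,6.681609e-03,1.657226e-01,1.080047e-02,0.000000e+00
62.7701,4.745323e-03,1.628807e-01,8.813127e-03,0.000000e+00
69.61401,3.370713e-03,1.598828e-01,7.188609e-03,0.000000e+00
77.20412,2.394687e-03,1.567327e-01,5.862361e-03,0.000000e+00
85.62178,1.701557e-03,1.534361e-01,4.780928e-03,0.000000e+00
94.95724,1.209247e-03,1.500008e-01,3.900208e-03,0.000000e+00
105.3106,8.595161e-04,1.464366e-01,3.183934e-03,0.000000e+00
116.7927,6.110313e-04,1.427549e-01,2.602365e-03,0.000000e+00
129.5268,4.344534e-04,1.389690e-01,2.131183e-03,0.000000e+00
143.6493,3.089536e-04,1.350934e-01,1.750547e-03,0.000000e+00
159.3115,2.197422e-04,1.311437e-01,1.444307e-03,0.000000e+00
176.6815,1.563162e-04,1.271362e-01,1.199326e-03,0.000000e+00
195.9453,1.112153e-04,1.230874e-01,1.004912e-03,0.000000e+00
217.3095,7.913984e-05,1.190138e-01,8.523136e-04,0.000000e+00
241.003,5.632434e-05,1.149311e-01,7.342912e-04,0.000000e+00
267.2799,4.009289e-05,1.108544e-01,6.447426e-04,0.000000e+00
296.4218,2.854361e-05,1.067974e-01,5.784081e-04,0.000000e+00
328.741,2.032455e-05,1.027725e-01,5.306660e-04,0.000000e+00
364.5841,1.447450e-05,9.879038e-02,4.974285e-04,0.000000e+00
404.3352,1.030996e-05,9.486043e-02,4.751247e-04,0.000000e+00
448.4204,7.344822e-06,9.099035e-02,4.607326e-04,0.000000e+00
497.3123,5.233312e-06,8.718647e-02,4.518116e-04,0.000000e+00
551.5349,3.729437e-06,8.345390e-02,4.464985e-04,0.000000e+00
611.6695,2.658161e-06,7.979667e-02,4.434537e-04,0.000000e+00
678.3607,1.894922e-06,7.621802e-02,4.417710e-04,0.000000e+00
752.3233,1.351055e-06,7.272056e-02,4.408714e-04,0.000000e+00
834.3501,9.634459e-07,6.930645e-02,4.404048e-04,0.000000e+00
925.3204,6.871541e-07,6.597759e-02,4.401690e-04,0.000000e+00
1026.209,4.901780e-07,6.273571e-02,4.400527e-04,0.000000e+00
1138.098,3.497250e-07,5.958248e-02,4.399964e-04,0.000000e+00
1262.187,2.495590e-07,5.651950e-02,4.399697e-04,0.000000e+00
1399.805,1.781121e-07,5.354838e-02,4.399571e-04,0.000000e+00
1552.427,1.271418e-07,5.067066e-02,4.399513e-04,0.000000e+00
1721.69,9.077317e-08,4.788782e-02,4.399487e-04,0.000000e+00
1909.409,6.481893e-08,4.520121e-02,4.399475e-04,0.000000e+00
2117.594,4.629367e-08,4.261203e-02,4.399469e-04,0.000000e+00
2348.478,3.306871e-08,4.012121e-02,4.399467e-04,0.000000e+00
2604.536,2.362594e-08,3.772943e-02,4.399466e-04,0.000000e+00
2888.512,1.688254e-08,3.543707e-02,4.399465e-04,0.000000e+00
3203.45,1.206600e-08,3.324414e-02,4.399465e-04,0.000000e+00
3552.727,8.625149e-09,3.115029e-02,4.399465e-04,1.204381e-04
3940.085,6.166629e-09,2.915482e-02,4.399465e-04,4.571855e-04
4369.678,4.409683e-09,2.725665e-02,4.399465e-04,7.939330e-04
4846.11,3.153885e-09,2.545434e-02,4.399465e-04,1.130680e-03
5374.488,2.256127e-09,2.374613e-02,4.399465e-04,1.467428e-03
5960.475,1.614213e-09,2.212992e-02,4.399465e-04,1.804175e-03
6610.354,1.155150e-09,2.060338e-02,4.399465e-04,2.140923e-03
7331.09,8.267928e-10,1.916390e-02,4.399465e-04,2.477670e-03
8130.408,5.918830e-10,1.780867e-02,4.399465e-04,2.814418e-03
9016.878,4.237956e-10,1.653471e-02,4.399465e-04,3.151165e-03
10000,3.035002e-10,1.533891e-02,4.399465e-04,3.487913e-03
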