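# synthetic photon mass attenuation table, element P (Z=15, A=30.974)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,1.806032e+03,1.932558e-01,2.857129e+00,0.000000e+00
1.109031,1.375110e+03,1.931739e-01,2.845172e+00,0.000000e+00
1.229951,1.045408e+03,1.930832e-01,2.830585e+00,0.000000e+00
1.364054,7.935590e+02,1.929827e-01,2.812822e+00,0.000000e+00
1.512778,6.014774e+02,1.928714e-01,2.791243e+00,0.000000e+00
1.677719,4.552000e+02,1.927481e-01,2.765098e+00,0.000000e+00
1.860642,3.439682e+02,1.926117e-01,2.733529e+00,0.000000e+00
2.063511,2.595086e+02,1.924607e-01,2.695563e+00,0.000000e+00
2.1455,2.332920e+02,1.923997e-01,2.679394e+00,0.000000e+00
2.1455,2.605796e+03,1.923997e-01,2.679393e+00,0.000000e+00
2.288498,2.254905e+03,1.922936e-01,2.650129e+00,0.000000e+00
2.538016,1.723757e+03,1.921087e-01,2.596082e+00,0.000000e+00
2.814739,1.317383e+03,1.919042e-01,2.532243e+00,0.000000e+00
3.121634,1.005441e+03,1.916780e-01,2.457479e+00,0.000000e+00
3.46199,7.646891e+02,1.914280e-01,2.370800e+00,0.000000e+00
3.839456,5.797790e+02,1.911517e-01,2.271491e+00,0.000000e+00
4.258077,4.382528e+02,1.908466e-01,2.159279e+00,0.000000e+00
4.722341,3.297031e+02,1.905096e-01,2.034493e+00,0.000000e+00
5.237224,2.474036e+02,1.901377e-01,1.898215e+00,0.000000e+00
5.808245,1.851994e+02,1.897275e-01,1.752374e+00,0.000000e+00
6.441526,1.382990e+02,1.892753e-01,1.599726e+00,0.000000e+00
7.143854,1.030240e+02,1.887771e-01,1.443713e+00,0.000000e+00
7.922758,7.655907e+01,1.882285e-01,1.288168e+00,0.000000e+00
8.786587,5.675333e+01,1.876250e-01,1.136931e+00,0.000000e+00
9.744601,4.192322e+01,1.869616e-01,9.934290e-01,0.000000e+00
10.80707,3.088526e+01,1.862331e-01,8.603402e-01,0.000000e+00
11.98538,2.272036e+01,1.854338e-01,7.393970e-01,0.000000e+00
13.29216,1.668948e+01,1.845580e-01,6.313771e-01,0.000000e+00
14.74142,1.224142e+01,1.835993e-01,5.362427e-01,0.000000e+00
16.3487,8.965588e+00,1.825514e-01,4.533665e-01,0.000000e+00
18.13122,6.556648e+00,1.814077e-01,3.817687e-01,0.000000e+00
20.10809,4.787831e+00,1.801613e-01,3.203129e-01,0.000000e+00
22.3005,3.490981e+00,1.788054e-01,2.678406e-01,0.000000e+00
24.73195,2.541594e+00,1.773332e-01,2.232468e-01,0.000000e+00
27.42851,1.846832e+00,1.757380e-01,1.855137e-01,0.000000e+00
30.41908,1.338742e+00,1.740133e-01,1.537207e-01,0.000000e+00
33.73571,9.694313e-01,1.721531e-01,1.270428e-01,0.000000e+00
37.41396,7.012720e-01,1.701519e-01,1.047454e-01,0.000000e+00
41.49326,5.067623e-01,1.680051e-01,8.617853e-02,0.000000e+00
46.01732,3.658222e-01,1.657087e-01,7.077097e-02,0.000000e+00
51.03465,2.638054e-01,1.632603e-01,5.802466e-02,0.000000e+00
56.59903,1.900402e-01,1.606585e-01,4.750890e-02,0.000000e+00
62.7701,1.367592e-01,1.579034e-01,3.885422e-02,0.000000e+00
69.61401,9.831449e-02,1.549971e-01,3.174616e-02,0.000000e+00
77.20412,7.060421e-02,1.519433e-01,2.591891e-02,0.000000e+00
85.62178,5.065214e-02,1.487474e-01,2.114919e-02,0.000000e+00
94.95724,3.630127e-02,1.454171e-01,1.725053e-02,0.000000e+00
105.3106,2.598998e-02,1.419618e-01,1.406787e-02,0.000000e+00
116.7927,1.858890e-02,1.383926e-01,1.147285e-02,0.000000e+00
129.5268,1.328219e-02,1.347224e-01,9.359602e-03,0.000000e+00
143.6493,9.481101e-03,1.309652e-01,7.641056e-03,0.000000e+00
159.3115,6.761244e-03,1.271362e-01,6.245835e-03,0.000000e+00
176.6815,4.817033e-03,1.232512e-01,5.115576e-03,0.000000e+00
195.9453,3.428664e-03,1.193261e-01,4.202670e-03,0.000000e+00
217.3095,2.438209e-03,1.153770e-01,3.468364e-03,0.000000e+00
241.003,1.732312e-03,1.114191e-01,2.881142e-03,0.000000e+00
267.2799,1.229706e-03,1.074670e-01,2.415342e-03,0.000000e+00
296.4218,8.721816e-04,1.035339e-01,2.049958e-03,0.000000e+00
328.741,6.180959e-04,9.963196e-02,1.767596e-03,0.000000e+00
364.5841,4.376853e-04,9.577155e-02,1.553581e-03,0.000000e+00
404.3352,3.096994e-04,9.196169e-02,1.395251e-03,0.000000e+00
448.4204,2.189818e-04,8.820988e-02,1.281471e-03,0.000000e+00
497.3123,1.547333e-04,8.452224e-02,1.202394e-03,0.000000e+00
551.5349,1.092668e-04,8.090372e-02,1.149429e-03,0.000000e+00
611.6695,7.711597e-05,7.735825e-02,1.115318e-03,0.000000e+00
678.3607,5.439726e-05,7.388896e-02,1.094216e-03,0.000000e+00
752.3233,3.835430e-05,7.049837e-02,1.081672e-03,0.000000e+00
834.3501,2.703248e-05,6.718859e-02,1.074496e-03,0.000000e+00
925.3204,1.904696e-05,6.396145e-02,1.070537e-03,0.000000e+00
1026.209,1.341746e-05,6.081864e-02,1.068424e-03,0.000000e+00
1138.098,9.450596e-06,5.776176e-02,1.067329e-03,0.000000e+00
1262.187,6.656351e-06,5.479239e-02,1.066777e-03,0.000000e+00
1399.805,4.688658e-06,5.191205e-02,1.066505e-03,0.000000e+00
1552.427,3.303296e-06,4.912227e-02,1.066373e-03,0.000000e+00
1721.69,2.328030e-06,4.642447e-02,1.066311e-03,0.000000e+00
1909.409,1.641463e-06,4.381996e-02,1.066281e-03,0.000000e+00
2117.594,1.158082e-06,4.130989e-02,1.066268e-03,0.000000e+00
2348.478,8.176755e-07,3.889519e-02,1.066262e-03,0.000000e+00
2604.536,5.778677e-07,3.657650e-02,1.066259e-03,0.000000e+00
2888.512,4.088438e-07,3.435419e-02,1.066258e-03,0.000000e+00
3203.45,2.896326e-07,3.222827e-02,1.066257e-03,0.000000e+00
3552.727,2.054853e-07,3.019840e-02,1.066257e-03,2.918943e-04
3940.085,1.460300e-07,2.826391e-02,1.066257e-03,1.108037e-03
4369.678,1.039721e-07,2.642374e-02,1.066257e-03,1.924180e-03
4846.11,7.418085e-08,2.467651e-02,1.066257e-03,2.740323e-03
5374.488,5.304595e-08,2.302049e-02,1.066257e-03,3.556466e-03
5960.475,3.802609e-08,2.145368e-02,1.066257e-03,4.372609e-03
6610.354,2.733130e-08,1.997379e-02,1.066257e-03,5.188752e-03
7331.09,1.969985e-08,1.857829e-02,1.066257e-03,6.004895e-03
8130.408,1.424161e-08,1.726447e-02,1.066257e-03,6.821038e-03
9016.878,1.032784e-08,1.602944e-02,1.066257e-03,7.637181e-03
10000,7.513924e-09,1.487019e-02,1.066257e-03,8.453324e-03
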