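# synthetic photon mass attenuation table, element K (Z=19, A=39.098)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,3.900144e+03,1.939267e-01,3.641289e+00,0.000000e+00
1.109031,2.989343e+03,1.938445e-01,3.628239e+00,0.000000e+00
1.229951,2.284892e+03,1.937535e-01,3.612299e+00,0.000000e+00
1.364054,1.741821e+03,1.936526e-01,3.592863e+00,0.000000e+00
1.512778,1.325488e+03,1.935409e-01,3.569207e+00,0.000000e+00
1.677719,1.006337e+03,1.934173e-01,3.540486e+00,0.000000e+00
1.860642,7.628481e+02,1.932804e-01,3.505714e+00,0.000000e+00
2.063511,5.774009e+02,1.931288e-01,3.463764e+00,0.000000e+00
2.288498,4.363889e+02,1.929611e-01,3.413370e+00,0.000000e+00
2.538016,3.293318e+02,1.927756e-01,3.353144e+00,0.000000e+00
2.814739,2.481755e+02,1.925704e-01,3.281613e+00,0.000000e+00
3.121634,1.866157e+02,1.923434e-01,3.197283e+00,0.000000e+00
3.46199,1.400106e+02,1.920926e-01,3.098744e+00,0.000000e+00
3.6074,1.248609e+02,1.919856e-01,3.055345e+00,0.000000e+00
3.6074,1.213350e+03,1.919856e-01,3.055343e+00,0.000000e+00
3.839456,1.029553e+03,1.918153e-01,2.984804e+00,0.000000e+00
4.258077,7.883263e+02,1.915091e-01,2.854670e+00,0.000000e+00
4.722341,6.017872e+02,1.911710e-01,2.708157e+00,0.000000e+00
5.237224,4.580108e+02,1.907978e-01,2.545896e+00,0.000000e+00
5.808245,3.474862e+02,1.903862e-01,2.369514e+00,0.000000e+00
6.441526,2.628021e+02,1.899324e-01,2.181721e+00,0.000000e+00
7.143854,1.981313e+02,1.894324e-01,1.986253e+00,0.000000e+00
7.922758,1.488530e+02,1.888819e-01,1.787640e+00,0.000000e+00
8.786587,1.115427e+02,1.882764e-01,1.590807e+00,0.000000e+00
9.744601,8.327026e+01,1.876107e-01,1.400554e+00,0.000000e+00
10.80707,6.202761e+01,1.868796e-01,1.221046e+00,0.000000e+00
11.98538,4.611169e+01,1.860776e-01,1.055412e+00,0.000000e+00
13.29216,3.421069e+01,1.851987e-01,9.055574e-01,0.000000e+00
14.74142,2.532983e+01,1.842367e-01,7.722024e-01,0.000000e+00
16.3487,1.870607e+01,1.831852e-01,6.550920e-01,0.000000e+00
18.13122,1.378160e+01,1.820374e-01,5.532954e-01,0.000000e+00
20.10809,1.013801e+01,1.807867e-01,4.655001e-01,0.000000e+00
22.3005,7.446251e+00,1.794261e-01,3.902425e-01,0.000000e+00
24.73195,5.460747e+00,1.779488e-01,3.260600e-01,0.000000e+00
27.42851,3.994694e+00,1.763481e-01,2.715719e-01,0.000000e+00
30.41908,2.911212e+00,1.746174e-01,2.255138e-01,0.000000e+00
33.73571,2.119832e+00,1.727508e-01,1.867448e-01,0.000000e+00
37.41396,1.542279e+00,1.707426e-01,1.542446e-01,0.000000e+00
41.49326,1.121130e+00,1.685883e-01,1.271056e-01,0.000000e+00
46.01732,8.142881e-01,1.662840e-01,1.045264e-01,0.000000e+00
51.03465,5.909175e-01,1.638271e-01,8.580363e-02,0.000000e+00
56.59903,4.284503e-01,1.612162e-01,7.032536e-02,0.000000e+00
62.7701,3.103823e-01,1.584516e-01,5.756345e-02,0.000000e+00
69.61401,2.246543e-01,1.555352e-01,4.706569e-02,0.000000e+00
77.20412,1.624623e-01,1.524707e-01,3.844784e-02,0.000000e+00
85.62178,1.173839e-01,1.492638e-01,3.138564e-02,0.000000e+00
94.95724,8.473878e-02,1.459220e-01,2.560711e-02,0.000000e+00
105.3106,6.111840e-02,1.424546e-01,2.088532e-02,0.000000e+00
116.7927,4.404301e-02,1.388731e-01,1.703183e-02,0.000000e+00
129.5268,3.171002e-02,1.351901e-01,1.389076e-02,0.000000e+00
143.6493,2.281023e-02,1.314199e-01,1.133362e-02,0.000000e+00
159.3115,1.639365e-02,1.275776e-01,9.254860e-03,0.000000e+00
176.6815,1.177157e-02,1.236791e-01,7.567979e-03,0.000000e+00
195.9453,8.445100e-03,1.197404e-01,6.202299e-03,0.000000e+00
217.3095,6.053224e-03,1.157775e-01,5.100197e-03,0.000000e+00
241.003,4.334907e-03,1.118059e-01,4.214785e-03,0.000000e+00
267.2799,3.101585e-03,1.078400e-01,3.507928e-03,0.000000e+00
296.4218,2.217166e-03,1.038934e-01,2.948551e-03,0.000000e+00
328.741,1.583518e-03,9.997784e-02,2.511163e-03,0.000000e+00
364.5841,1.129947e-03,9.610404e-02,2.174575e-03,0.000000e+00
404.3352,8.055700e-04,9.228095e-02,1.920817e-03,0.000000e+00
448.4204,5.737975e-04,8.851611e-02,1.734300e-03,0.000000e+00
497.3123,4.083421e-04,8.481567e-02,1.601281e-03,0.000000e+00
551.5349,2.903354e-04,8.118459e-02,1.509618e-03,0.000000e+00
611.6695,2.062462e-04,7.762681e-02,1.448785e-03,0.000000e+00
678.3607,1.463802e-04,7.414547e-02,1.409980e-03,0.000000e+00
752.3233,1.037981e-04,7.074311e-02,1.386203e-03,0.000000e+00
834.3501,7.353719e-05,6.742184e-02,1.372200e-03,0.000000e+00
925.3204,5.205179e-05,6.418350e-02,1.364261e-03,0.000000e+00
1026.209,3.681083e-05,6.102978e-02,1.359916e-03,0.000000e+00
1138.098,2.600920e-05,5.796229e-02,1.357615e-03,0.000000e+00
1262.187,1.836074e-05,5.498260e-02,1.356430e-03,0.000000e+00
1399.805,1.294987e-05,5.209227e-02,1.355836e-03,0.000000e+00
1552.427,9.125422e-06,4.929280e-02,1.355544e-03,0.000000e+00
1721.69,6.424708e-06,4.658563e-02,1.355404e-03,0.000000e+00
1909.409,4.519256e-06,4.397209e-02,1.355338e-03,0.000000e+00
2117.594,3.176098e-06,4.145330e-02,1.355307e-03,0.000000e+00
2348.478,2.230154e-06,3.903022e-02,1.355292e-03,0.000000e+00
2604.536,1.564553e-06,3.670348e-02,1.355286e-03,0.000000e+00
2888.512,1.096630e-06,3.447345e-02,1.355283e-03,0.000000e+00
3203.45,7.679717e-07,3.234015e-02,1.355282e-03,0.000000e+00
3552.727,5.373359e-07,3.030324e-02,1.355281e-03,3.710164e-04
3940.085,3.756320e-07,2.836203e-02,1.355281e-03,1.408386e-03
4369.678,2.623588e-07,2.651548e-02,1.355281e-03,2.445756e-03
4846.11,1.830820e-07,2.476218e-02,1.355280e-03,3.483126e-03
5374.488,1.276477e-07,2.310041e-02,1.355280e-03,4.520496e-03
5960.475,8.891970e-08,2.152816e-02,1.355280e-03,5.557866e-03
6610.354,6.188726e-08,2.004313e-02,1.355280e-03,6.595236e-03
7331.09,4.303513e-08,1.864279e-02,1.355280e-03,7.632606e-03
8130.408,2.989951e-08,1.732441e-02,1.355280e-03,8.669976e-03
9016.878,2.075509e-08,1.608509e-02,1.355280e-03,9.707346e-03
10000,1.439478e-08,1.492181e-02,1.355280e-03,1.074472e-02
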