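# synthetic photon mass attenuation table, element N (Z=7, A=14.007)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,3.169275e+03,1.994305e-01,1.359461e+00,0.000000e+00
1.109031,2.387381e+03,1.993459e-01,1.350112e+00,0.000000e+00
1.229951,1.793927e+03,1.992523e-01,1.338768e+00,0.000000e+00
1.364054,1.344647e+03,1.991486e-01,1.325043e+00,0.000000e+00
1.512778,1.005381e+03,1.990337e-01,1.308500e+00,0.000000e+00
1.677719,7.494297e+02,1.989066e-01,1.288647e+00,0.000000e+00
1.860642,5.570075e+02,1.987658e-01,1.264950e+00,0.000000e+00
2.063511,4.131546e+02,1.986099e-01,1.236848e+00,0.000000e+00
2.288498,3.058331e+02,1.984375e-01,1.203776e+00,0.000000e+00
2.538016,2.259312e+02,1.982467e-01,1.165214e+00,0.000000e+00
2.814739,1.665663e+02,1.980356e-01,1.120737e+00,0.000000e+00
3.121634,1.224837e+02,1.978022e-01,1.070086e+00,0.000000e+00
3.46199,8.982659e+01,1.975443e-01,1.013253e+00,0.000000e+00
3.839456,6.576446e+01,1.972592e-01,9.505527e-01,0.000000e+00
4.258077,4.806586e+01,1.969442e-01,8.826896e-01,0.000000e+00
4.722341,3.507037e+01,1.965965e-01,8.107780e-01,0.000000e+00
5.237224,2.554483e+01,1.962128e-01,7.363085e-01,0.000000e+00
5.808245,1.857481e+01,1.957895e-01,6.610450e-01,0.000000e+00
6.441526,1.348354e+01,1.953228e-01,5.868599e-01,0.000000e+00
7.143854,9.771044e+00,1.948086e-01,5.155359e-01,0.000000e+00
7.922758,7.067877e+00,1.942425e-01,4.485761e-01,0.000000e+00
8.786587,5.104711e+00,1.936197e-01,3.870691e-01,0.000000e+00
9.744601,3.673774e+00,1.929352e-01,3.316360e-01,0.000000e+00
10.80707,2.641073e+00,1.921834e-01,2.824608e-01,0.000000e+00
11.98538,1.897264e+00,1.913586e-01,2.393816e-01,0.000000e+00
13.29216,1.361916e+00,1.904547e-01,2.020058e-01,0.000000e+00
14.74142,9.769067e-01,1.894654e-01,1.698172e-01,0.000000e+00
16.3487,7.002225e-01,1.883840e-01,1.422576e-01,0.000000e+00
18.13122,5.015325e-01,1.872038e-01,1.187776e-01,0.000000e+00
20.10809,3.589568e-01,1.859175e-01,9.886310e-02,0.000000e+00
22.3005,2.567232e-01,1.845184e-01,8.204505e-02,0.000000e+00
24.73195,1.834713e-01,1.829991e-01,6.790131e-02,0.000000e+00
27.42851,1.309109e-01,1.813529e-01,5.605475e-02,0.000000e+00
30.41908,9.314782e-02,1.795732e-01,4.617050e-02,0.000000e+00
33.73571,6.627184e-02,1.776535e-01,3.795310e-02,0.000000e+00
37.41396,4.714597e-02,1.755884e-01,3.114385e-02,0.000000e+00
41.49326,3.353659e-02,1.733730e-01,2.551800e-02,0.000000e+00
46.01732,2.385348e-02,1.710033e-01,2.088192e-02,0.000000e+00
51.03465,1.696458e-02,1.684766e-01,1.707012e-02,0.000000e+00
56.59903,1.206403e-02,1.657916e-01,1.394218e-02,0.000000e+00
62.7701,8.578263e-03,1.629486e-01,1.137977e-02,0.000000e+00
69.61401,6.099076e-03,1.599494e-01,9.283757e-03,0.000000e+00
77.20412,4.335969e-03,1.567979e-01,7.571526e-03,0.000000e+00
85.62178,3.082234e-03,1.535000e-01,6.174524e-03,0.000000e+00
94.95724,2.190796e-03,1.500633e-01,5.036096e-03,0.000000e+00
105.3106,1.557024e-03,1.464976e-01,4.109576e-03,0.000000e+00
116.7927,1.106485e-03,1.428144e-01,3.356647e-03,0.000000e+00
129.5268,7.862355e-04,1.390269e-01,2.745931e-03,0.000000e+00
143.6493,5.586197e-04,1.351497e-01,2.251803e-03,0.000000e+00
159.3115,3.968592e-04,1.311983e-01,1.853379e-03,0.000000e+00
176.6815,2.819117e-04,1.271891e-01,1.533671e-03,0.000000e+00
195.9453,2.002379e-04,1.231387e-01,1.278861e-03,0.000000e+00
217.3095,1.422120e-04,1.190634e-01,1.077678e-03,0.000000e+00
241.003,1.009909e-04,1.149790e-01,9.208544e-04,0.000000e+00
267.2799,7.171089e-05,1.109006e-01,8.006581e-04,0.000000e+00
296.4218,5.091485e-05,1.068419e-01,7.104991e-04,0.000000e+00
328.741,3.614602e-05,1.028153e-01,6.446359e-04,0.000000e+00
364.5841,2.565862e-05,9.883152e-02,5.979961e-04,0.000000e+00
404.3352,1.821222e-05,9.489993e-02,5.661099e-04,0.000000e+00
448.4204,1.292556e-05,9.102824e-02,5.451260e-04,0.000000e+00
497.3123,9.172613e-06,8.722278e-02,5.318563e-04,0.000000e+00
551.5349,6.508696e-06,8.348865e-02,5.237958e-04,0.000000e+00
611.6695,4.617982e-06,7.982990e-02,5.190884e-04,0.000000e+00
678.3607,3.276183e-06,7.624976e-02,5.164404e-04,0.000000e+00
752.3233,2.324031e-06,7.275084e-02,5.150019e-04,0.000000e+00
834.3501,1.648442e-06,6.933531e-02,5.142447e-04,0.000000e+00
925.3204,1.169132e-06,6.600507e-02,5.138573e-04,0.000000e+00
1026.209,8.291097e-07,6.276184e-02,5.136640e-04,0.000000e+00
1138.098,5.879213e-07,5.960729e-02,5.135696e-04,0.000000e+00
1262.187,4.168553e-07,5.654304e-02,5.135243e-04,0.000000e+00
1399.805,2.955363e-07,5.357068e-02,5.135030e-04,0.000000e+00
1552.427,2.095057e-07,5.069176e-02,5.134930e-04,0.000000e+00
1721.69,1.485049e-07,4.790776e-02,5.134885e-04,0.000000e+00
1909.409,1.052558e-07,4.522004e-02,5.134864e-04,0.000000e+00
2117.594,7.459535e-08,4.262977e-02,5.134854e-04,0.000000e+00
2348.478,5.286136e-08,4.013792e-02,5.134850e-04,0.000000e+00
2604.536,3.745640e-08,3.774515e-02,5.134848e-04,0.000000e+00
2888.512,2.653844e-08,3.545183e-02,5.134847e-04,0.000000e+00
3203.45,1.880124e-08,3.325798e-02,5.134847e-04,0.000000e+00
3552.727,1.331865e-08,3.116326e-02,5.134847e-04,1.405696e-04
3940.085,9.434007e-09,2.916696e-02,5.134847e-04,5.336053e-04
4369.678,6.681828e-09,2.726800e-02,5.134847e-04,9.266409e-04
4846.11,4.732142e-09,2.546494e-02,5.134846e-04,1.319677e-03
5374.488,3.351074e-09,2.375601e-02,5.134846e-04,1.712712e-03
5960.475,2.372873e-09,2.213914e-02,5.134846e-04,2.105748e-03
6610.354,1.680077e-09,2.061196e-02,5.134846e-04,2.498784e-03
7331.09,1.189458e-09,1.917188e-02,5.134846e-04,2.891819e-03
8130.408,8.420427e-10,1.781608e-02,5.134846e-04,3.284855e-03
9016.878,5.960529e-10,1.654160e-02,5.134846e-04,3.677891e-03
10000,4.218922e-10,1.534530e-02,5.134846e-04,4.070926e-03
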