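# synthetic photon mass attenuation table, element O (Z=8, A=15.999)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,4.419154e+03,1.995427e-01,1.558536e+00,0.000000e+00
1.109031,3.356436e+03,1.994581e-01,1.548707e+00,0.000000e+00
1.229951,2.542219e+03,1.993644e-01,1.536767e+00,0.000000e+00
1.364054,1.920178e+03,1.992606e-01,1.522301e+00,0.000000e+00
1.512778,1.446316e+03,1.991457e-01,1.504836e+00,0.000000e+00
1.677719,1.086368e+03,1.990185e-01,1.483834e+00,0.000000e+00
1.860642,8.137316e+02,1.988776e-01,1.458705e+00,0.000000e+00
2.063511,6.078206e+02,1.987217e-01,1.428816e+00,0.000000e+00
2.288498,4.524557e+02,1.985491e-01,1.393520e+00,0.000000e+00
2.538016,3.359752e+02,1.983582e-01,1.352192e+00,0.000000e+00
2.814739,2.489620e+02,1.981470e-01,1.304291e+00,0.000000e+00
3.121634,1.839862e+02,1.979135e-01,1.249428e+00,0.000000e+00
3.46199,1.355794e+02,1.976554e-01,1.187460e+00,0.000000e+00
3.839456,9.973165e+01,1.973701e-01,1.118576e+00,0.000000e+00
4.258077,7.323238e+01,1.970550e-01,1.043385e+00,0.000000e+00
4.722341,5.367884e+01,1.967071e-01,9.629597e-01,0.000000e+00
5.237224,3.927642e+01,1.963231e-01,8.788293e-01,0.000000e+00
5.808245,2.868723e+01,1.958996e-01,7.928958e-01,0.000000e+00
6.441526,2.091569e+01,1.954326e-01,7.072736e-01,0.000000e+00
7.143854,1.522237e+01,1.949182e-01,6.240737e-01,0.000000e+00
7.922758,1.105905e+01,1.943518e-01,5.451759e-01,0.000000e+00
8.786587,8.020073e+00,1.937287e-01,4.720424e-01,0.000000e+00
9.744601,5.805390e+00,1.930437e-01,4.056141e-01,0.000000e+00
10.80707,4.190351e+00,1.922915e-01,3.463069e-01,0.000000e+00
11.98538,3.020299e+00,1.914662e-01,2.940904e-01,0.000000e+00
13.29216,2.175119e+00,1.905619e-01,2.486127e-01,0.000000e+00
14.74142,1.565126e+00,1.895720e-01,2.093309e-01,0.000000e+00
16.3487,1.125248e+00,1.884900e-01,1.756184e-01,0.000000e+00
18.13122,8.083144e-01,1.873091e-01,1.468374e-01,0.000000e+00
20.10809,5.801559e-01,1.860221e-01,1.223804e-01,0.000000e+00
22.3005,4.160461e-01,1.846222e-01,1.016883e-01,0.000000e+00
24.73195,2.981058e-01,1.831021e-01,8.425544e-02,0.000000e+00
27.42851,2.132263e-01,1.814550e-01,6.962877e-02,0.000000e+00
30.41908,1.520602e-01,1.796742e-01,5.740497e-02,0.000000e+00
33.73571,1.084210e-01,1.777535e-01,4.722721e-02,0.000000e+00
37.41396,7.729188e-02,1.756872e-01,3.878196e-02,0.000000e+00
41.49326,5.509046e-02,1.734705e-01,3.179591e-02,0.000000e+00
46.01732,3.925913e-02,1.710994e-01,2.603275e-02,0.000000e+00
51.03465,2.797218e-02,1.685714e-01,2.128983e-02,0.000000e+00
56.59903,1.992660e-02,1.658849e-01,1.739467e-02,0.000000e+00
62.7701,1.419256e-02,1.630402e-01,1.420151e-02,0.000000e+00
69.61401,1.010669e-02,1.600394e-01,1.158795e-02,0.000000e+00
77.20412,7.195773e-03,1.568861e-01,9.451743e-03,0.000000e+00
85.62178,5.122313e-03,1.535863e-01,7.707914e-03,0.000000e+00
94.95724,3.645648e-03,1.501477e-01,6.286109e-03,0.000000e+00
105.3106,2.594199e-03,1.465800e-01,5.128299e-03,0.000000e+00
116.7927,1.845659e-03,1.428947e-01,4.186775e-03,0.000000e+00
129.5268,1.312863e-03,1.391051e-01,3.422424e-03,0.000000e+00
143.6493,9.336986e-04,1.352257e-01,2.803267e-03,0.000000e+00
159.3115,6.639169e-04,1.312721e-01,2.303220e-03,0.000000e+00
176.6815,4.719981e-04,1.272607e-01,1.901050e-03,0.000000e+00
195.9453,3.354953e-04,1.232080e-01,1.579491e-03,0.000000e+00
217.3095,2.384252e-04,1.191303e-01,1.324482e-03,0.000000e+00
241.003,1.694095e-04,1.150437e-01,1.124512e-03,0.000000e+00
267.2799,1.203492e-04,1.109630e-01,9.700440e-04,0.000000e+00
296.4218,8.548078e-05,1.069020e-01,8.530291e-04,0.000000e+00
328.741,6.070354e-05,1.028731e-01,7.665177e-04,0.000000e+00
364.5841,4.310026e-05,9.888712e-02,7.043968e-04,0.000000e+00
404.3352,3.059612e-05,9.495332e-02,6.612608e-04,0.000000e+00
448.4204,2.171569e-05,9.107945e-02,6.323958e-04,0.000000e+00
497.3123,1.540997e-05,8.727185e-02,6.138245e-04,0.000000e+00
551.5349,1.093331e-05,8.353562e-02,6.023470e-04,0.000000e+00
611.6695,7.755734e-06,7.987481e-02,5.955310e-04,0.000000e+00
678.3607,5.500678e-06,7.629265e-02,5.916357e-04,0.000000e+00
752.3233,3.900604e-06,7.279177e-02,5.894883e-04,0.000000e+00
834.3501,2.765478e-06,6.937431e-02,5.883430e-04,0.000000e+00
925.3204,1.960341e-06,6.604220e-02,5.877502e-04,0.000000e+00
1026.209,1.389366e-06,6.279715e-02,5.874512e-04,0.000000e+00
1138.098,9.845220e-07,5.964082e-02,5.873039e-04,0.000000e+00
1262.187,6.975231e-07,5.657485e-02,5.872328e-04,0.000000e+00
1399.805,4.941020e-07,5.360081e-02,5.871990e-04,0.000000e+00
1552.427,3.499450e-07,5.072027e-02,5.871831e-04,0.000000e+00
1721.69,2.478042e-07,4.793471e-02,5.871758e-04,0.000000e+00
1909.409,1.754461e-07,4.524548e-02,5.871725e-04,0.000000e+00
2117.594,1.241954e-07,4.265375e-02,5.871710e-04,0.000000e+00
2348.478,8.790112e-08,4.016049e-02,5.871703e-04,0.000000e+00
2604.536,6.220295e-08,3.776638e-02,5.871700e-04,0.000000e+00
2888.512,4.401044e-08,3.547177e-02,5.871698e-04,0.000000e+00
3203.45,3.113358e-08,3.327669e-02,5.871698e-04,0.000000e+00
3552.727,2.202073e-08,3.118080e-02,5.871697e-04,1.607413e-04
3940.085,1.557270e-08,2.918337e-02,5.871697e-04,6.101776e-04
4369.678,1.101099e-08,2.728334e-02,5.871697e-04,1.059614e-03
4846.11,7.784301e-09,2.547927e-02,5.871697e-04,1.509050e-03
5374.488,5.502296e-09,2.376938e-02,5.871697e-04,1.958487e-03
5960.475,3.888661e-09,2.215159e-02,5.871697e-04,2.407923e-03
6610.354,2.747821e-09,2.062356e-02,5.871697e-04,2.857359e-03
7331.09,1.941375e-09,1.918267e-02,5.871697e-04,3.306795e-03
8130.408,1.371398e-09,1.782611e-02,5.871697e-04,3.756232e-03
9016.878,9.686156e-10,1.655090e-02,5.871697e-04,4.205668e-03
10000,6.840273e-10,1.535393e-02,5.871697e-04,4.655104e-03
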