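# synthetic photon mass attenuation table, element Fe (Z=26, A=55.845)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,8.831954e+03,1.857923e-01,4.787928e+00,0.000000e+00
1.109031,6.904881e+03,1.857135e-01,4.773967e+00,0.000000e+00
1.229951,5.373138e+03,1.856263e-01,4.756893e+00,0.000000e+00
1.364054,4.156566e+03,1.855297e-01,4.736039e+00,0.000000e+00
1.512778,3.204788e+03,1.854227e-01,4.710608e+00,0.000000e+00
1.677719,2.463252e+03,1.853042e-01,4.679658e+00,0.000000e+00
1.860642,1.888261e+03,1.851730e-01,4.642078e+00,0.000000e+00
2.063511,1.443749e+03,1.850279e-01,4.596580e+00,0.000000e+00
2.288498,1.101103e+03,1.848672e-01,4.541688e+00,0.000000e+00
2.538016,8.377239e+02,1.846894e-01,4.475744e+00,0.000000e+00
2.814739,6.358244e+02,1.844928e-01,4.396929e+00,0.000000e+00
3.121634,4.811878e+02,1.842754e-01,4.303312e+00,0.000000e+00
3.46199,3.632072e+02,1.840351e-01,4.192937e+00,0.000000e+00
3.839456,2.736789e+02,1.837695e-01,4.063950e+00,0.000000e+00
4.258077,2.059901e+02,1.834761e-01,3.914786e+00,0.000000e+00
4.722341,1.548728e+02,1.831521e-01,3.744400e+00,0.000000e+00
5.237224,1.163130e+02,1.827946e-01,3.552536e+00,0.000000e+00
5.808245,8.725725e+01,1.824003e-01,3.340013e+00,0.000000e+00
6.441526,6.538620e+01,1.819655e-01,3.108948e+00,0.000000e+00
7.112,4.955796e+01,1.815081e-01,2.873756e+00,0.000000e+00
7.112,4.186899e+02,1.815081e-01,2.873751e+00,0.000000e+00
7.143854,4.130299e+02,1.814865e-01,2.862878e+00,0.000000e+00
7.922758,3.116640e+02,1.809591e-01,2.606690e+00,0.000000e+00
8.786587,2.381869e+02,1.803789e-01,2.346315e+00,0.000000e+00
9.744601,1.809581e+02,1.797412e-01,2.088205e+00,0.000000e+00
10.80707,1.371340e+02,1.790408e-01,1.838661e+00,0.000000e+00
11.98538,1.036451e+02,1.782724e-01,1.603153e+00,0.000000e+00
13.29216,7.812297e+01,1.774303e-01,1.385800e+00,0.000000e+00
14.74142,5.868972e+01,1.765087e-01,1.189118e+00,0.000000e+00
16.3487,4.394011e+01,1.755013e-01,1.014064e+00,0.000000e+00
18.13122,3.282409e+01,1.744017e-01,8.603154e-01,0.000000e+00
20.10809,2.446735e+01,1.732034e-01,7.266595e-01,0.000000e+00
22.3005,1.819856e+01,1.718999e-01,6.113786e-01,0.000000e+00
24.73195,1.350631e+01,1.704846e-01,5.125549e-01,0.000000e+00
27.42851,9.999363e+00,1.689510e-01,4.282703e-01,0.000000e+00
30.41908,7.384404e+00,1.672929e-01,3.567131e-01,0.000000e+00
33.73571,5.433128e+00,1.655046e-01,2.962240e-01,0.000000e+00
37.41396,3.992039e+00,1.635807e-01,2.453057e-01,0.000000e+00
41.49326,2.930180e+00,1.615167e-01,2.026189e-01,0.000000e+00
46.01732,2.148546e+00,1.593091e-01,1.669724e-01,0.000000e+00
51.03465,1.573772e+00,1.569552e-01,1.373139e-01,0.000000e+00
56.59903,1.151550e+00,1.544538e-01,1.127202e-01,0.000000e+00
62.7701,8.417144e-01,1.518052e-01,9.238774e-02,0.000000e+00
69.61401,6.145888e-01,1.490111e-01,7.562311e-02,0.000000e+00
77.20412,4.482706e-01,1.460752e-01,6.183247e-02,0.000000e+00
85.62178,3.266099e-01,1.430028e-01,5.051120e-02,0.000000e+00
94.95724,2.377115e-01,1.398011e-01,4.123344e-02,0.000000e+00
105.3106,1.728229e-01,1.364792e-01,3.364195e-02,0.000000e+00
116.7927,1.255107e-01,1.330479e-01,2.743866e-02,0.000000e+00
129.5268,9.105160e-02,1.295194e-01,2.237603e-02,0.000000e+00
143.6493,6.598127e-02,1.259074e-01,1.824932e-02,0.000000e+00
159.3115,4.776161e-02,1.222262e-01,1.488973e-02,0.000000e+00
176.6815,3.453518e-02,1.184912e-01,1.215859e-02,0.000000e+00
195.9453,2.494413e-02,1.147178e-01,9.942264e-03,0.000000e+00
217.3095,1.799692e-02,1.109211e-01,8.147904e-03,0.000000e+00
241.003,1.297033e-02,1.071161e-01,6.699802e-03,0.000000e+00
267.2799,9.337404e-03,1.033166e-01,5.536355e-03,0.000000e+00
296.4218,6.714655e-03,9.953544e-02,4.607461e-03,0.000000e+00
328.741,4.823290e-03,9.578417e-02,3.872297e-03,0.000000e+00
364.5841,3.460870e-03,9.207286e-02,3.297375e-03,0.000000e+00
404.3352,2.480558e-03,8.841013e-02,2.854867e-03,0.000000e+00
448.4204,1.775970e-03,8.480321e-02,2.521175e-03,0.000000e+00
497.3123,1.270120e-03,8.125799e-02,2.275836e-03,0.000000e+00
551.5349,9.073527e-04,7.777922e-02,2.100807e-03,0.000000e+00
611.6695,6.474865e-04,7.437068e-02,1.980151e-03,0.000000e+00
678.3607,4.615393e-04,7.103537e-02,1.900045e-03,0.000000e+00
752.3233,3.286323e-04,6.777572e-02,1.848924e-03,0.000000e+00
834.3501,2.337417e-04,6.459377e-02,1.817587e-03,0.000000e+00
925.3204,1.660682e-04,6.149126e-02,1.799125e-03,0.000000e+00
1026.209,1.178588e-04,5.846983e-02,1.788654e-03,0.000000e+00
1138.098,8.355325e-05,5.553101e-02,1.782922e-03,0.000000e+00
1262.187,5.916853e-05,5.267630e-02,1.779884e-03,0.000000e+00
1399.805,4.185477e-05,4.990721e-02,1.778320e-03,0.000000e+00
1552.427,2.957512e-05,4.722517e-02,1.777535e-03,0.000000e+00
1721.69,2.087546e-05,4.463155e-02,1.777150e-03,0.000000e+00
1909.409,1.471886e-05,4.212763e-02,1.776965e-03,0.000000e+00
2117.594,1.036673e-05,3.971451e-02,1.776877e-03,0.000000e+00
2348.478,7.293550e-06,3.739306e-02,1.776836e-03,0.000000e+00
2604.536,5.125861e-06,3.516392e-02,1.776817e-03,0.000000e+00
2888.512,3.598536e-06,3.302743e-02,1.776809e-03,0.000000e+00
3203.45,2.523578e-06,3.098361e-02,1.776805e-03,0.000000e+00
3552.727,1.767828e-06,2.903214e-02,1.776803e-03,4.864104e-04
3940.085,1.237077e-06,2.717236e-02,1.776802e-03,1.846424e-03
4369.678,8.647433e-07,2.540326e-02,1.776802e-03,3.206439e-03
4846.11,6.038266e-07,2.372350e-02,1.776802e-03,4.566453e-03
5374.488,4.211846e-07,2.213144e-02,1.776802e-03,5.926467e-03
5960.475,2.934733e-07,2.062514e-02,1.776802e-03,7.286481e-03
6610.354,2.042684e-07,1.920240e-02,1.776802e-03,8.646495e-03
7331.09,1.420271e-07,1.786080e-02,1.776802e-03,1.000651e-02
8130.408,9.864591e-08,1.659772e-02,1.776802e-03,1.136652e-02
9016.878,6.844246e-08,1.541039e-02,1.776802e-03,1.272654e-02
10000,4.743636e-08,1.429590e-02,1.776802e-03,1.408655e-02
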