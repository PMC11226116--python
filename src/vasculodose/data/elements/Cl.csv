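# synthetic photon mass attenuation table, element Cl (Z=17, A=35.45)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,2.687499e+03,1.913689e-01,3.211158e+00,0.000000e+00
1.109031,2.052251e+03,1.912878e-01,3.198778e+00,0.000000e+00
1.229951,1.563742e+03,1.911979e-01,3.183665e+00,0.000000e+00
1.364054,1.189569e+03,1.910984e-01,3.165248e+00,0.000000e+00
1.512778,9.034911e+02,1.909882e-01,3.142851e+00,0.000000e+00
1.677719,6.851437e+02,1.908661e-01,3.115684e+00,0.000000e+00
1.860642,5.187664e+02,1.907310e-01,3.082833e+00,0.000000e+00
2.063511,3.921910e+02,1.905815e-01,3.043258e+00,0.000000e+00
2.288498,2.960441e+02,1.904160e-01,2.995799e+00,0.000000e+00
2.538016,2.231207e+02,1.902329e-01,2.939199e+00,0.000000e+00
2.814739,1.678938e+02,1.900304e-01,2.872143e+00,0.000000e+00
2.8224,1.666413e+02,1.900248e-01,2.870230e+00,0.000000e+00
2.8224,1.722472e+03,1.900248e-01,2.870229e+00,0.000000e+00
3.121634,1.337924e+03,1.898065e-01,2.793327e+00,0.000000e+00
3.46199,1.023633e+03,1.895589e-01,2.701558e+00,0.000000e+00
3.839456,7.812383e+02,1.892853e-01,2.595891e+00,0.000000e+00
4.258077,5.946393e+02,1.889831e-01,2.475795e+00,0.000000e+00
4.722341,4.512244e+02,1.886495e-01,2.341345e+00,0.000000e+00
5.237224,3.413307e+02,1.882812e-01,2.193398e+00,0.000000e+00
5.808245,2.572932e+02,1.878750e-01,2.033730e+00,0.000000e+00
6.441526,1.932428e+02,1.874272e-01,1.865071e+00,0.000000e+00
7.143854,1.447792e+02,1.869338e-01,1.691004e+00,0.000000e+00
7.922758,1.082011e+02,1.863906e-01,1.515700e+00,0.000000e+00
8.786587,8.066303e+01,1.857930e-01,1.343524e+00,0.000000e+00
9.744601,5.993716e+01,1.851361e-01,1.178560e+00,0.000000e+00
10.80707,4.444464e+01,1.844147e-01,1.024192e+00,0.000000e+00
11.98538,3.289293e+01,1.836233e-01,8.828027e-01,0.000000e+00
13.29216,2.426615e+01,1.827559e-01,7.556871e-01,0.000000e+00
14.74142,1.786894e+01,1.818066e-01,6.431445e-01,0.000000e+00
16.3487,1.313842e+01,1.807690e-01,5.447048e-01,0.000000e+00
18.13122,9.645648e+00,1.796364e-01,4.593977e-01,0.000000e+00
20.10809,7.070667e+00,1.784022e-01,3.859967e-01,0.000000e+00
22.3005,5.175203e+00,1.770595e-01,3.231981e-01,0.000000e+00
24.73195,3.782074e+00,1.756017e-01,2.697307e-01,0.000000e+00
27.42851,2.758499e+00,1.740221e-01,2.244105e-01,0.000000e+00
30.41908,2.006854e+00,1.723142e-01,1.861600e-01,0.000000e+00
33.73571,1.458392e+00,1.704722e-01,1.540106e-01,0.000000e+00
37.41396,1.058632e+00,1.684906e-01,1.270980e-01,0.000000e+00
41.49326,7.675822e-01,1.663647e-01,1.046551e-01,0.000000e+00
46.01732,5.559188e-01,1.640908e-01,8.600603e-02,0.000000e+00
51.03465,4.021632e-01,1.616662e-01,7.055945e-02,0.000000e+00
56.59903,2.906002e-01,1.590898e-01,5.780234e-02,0.000000e+00
62.7701,2.097445e-01,1.563617e-01,4.729321e-02,0.000000e+00
69.61401,1.512115e-01,1.534837e-01,3.865512e-02,0.000000e+00
77.20412,1.088873e-01,1.504597e-01,3.156856e-02,0.000000e+00
85.62178,7.831901e-02,1.472950e-01,2.576455e-02,0.000000e+00
94.95724,5.626699e-02,1.439973e-01,2.101790e-02,0.000000e+00
105.3106,4.037717e-02,1.405757e-01,1.714105e-02,0.000000e+00
116.7927,2.894097e-02,1.370414e-01,1.397849e-02,0.000000e+00
129.5268,2.071977e-02,1.334070e-01,1.140175e-02,0.000000e+00
143.6493,1.481668e-02,1.296865e-01,9.305051e-03,0.000000e+00
159.3115,1.058304e-02,1.258949e-01,7.601594e-03,0.000000e+00
176.6815,7.550282e-03,1.220478e-01,6.220316e-03,0.000000e+00
195.9453,5.380333e-03,1.181610e-01,5.103198e-03,0.000000e+00
217.3095,3.829552e-03,1.142504e-01,4.202979e-03,0.000000e+00
241.003,2.722572e-03,1.103312e-01,3.481214e-03,0.000000e+00
267.2799,1.933318e-03,1.064177e-01,2.906627e-03,0.000000e+00
296.4218,1.371260e-03,1.025230e-01,2.453688e-03,0.000000e+00
328.741,9.714685e-04,9.865915e-02,2.101372e-03,0.000000e+00
364.5841,6.874324e-04,9.483644e-02,1.832089e-03,0.000000e+00
404.3352,4.858740e-04,9.106378e-02,1.630796e-03,0.000000e+00
448.4204,3.430123e-04,8.734860e-02,1.484356e-03,0.000000e+00
497.3123,2.418735e-04,8.369697e-02,1.381150e-03,0.000000e+00
551.5349,1.703568e-04,8.011378e-02,1.310962e-03,0.000000e+00
611.6695,1.198459e-04,7.660293e-02,1.265029e-03,0.000000e+00
678.3607,8.421315e-05,7.316751e-02,1.236148e-03,0.000000e+00
752.3233,5.910573e-05,6.981002e-02,1.218703e-03,0.000000e+00
834.3501,4.143549e-05,6.653256e-02,1.208571e-03,0.000000e+00
925.3204,2.901407e-05,6.333693e-02,1.202901e-03,0.000000e+00
1026.209,2.029264e-05,6.022481e-02,1.199835e-03,0.000000e+00
1138.098,1.417628e-05,5.719778e-02,1.198228e-03,0.000000e+00
1262.187,9.891910e-06,5.425739e-02,1.197409e-03,0.000000e+00
1399.805,6.894337e-06,5.140518e-02,1.197001e-03,0.000000e+00
1552.427,4.799541e-06,4.864264e-02,1.196803e-03,0.000000e+00
1721.69,3.337352e-06,4.597118e-02,1.196708e-03,0.000000e+00
1909.409,2.317928e-06,4.339210e-02,1.196663e-03,0.000000e+00
2117.594,1.608029e-06,4.090654e-02,1.196643e-03,0.000000e+00
2348.478,1.114254e-06,3.851542e-02,1.196633e-03,0.000000e+00
2604.536,7.712076e-07,3.621937e-02,1.196629e-03,0.000000e+00
2888.512,5.331581e-07,3.401875e-02,1.196627e-03,0.000000e+00
3203.45,3.681619e-07,3.191359e-02,1.196626e-03,0.000000e+00
3552.727,2.539338e-07,2.990355e-02,1.196625e-03,3.275835e-04
3940.085,1.749450e-07,2.798794e-02,1.196625e-03,1.243514e-03
4369.678,1.203878e-07,2.616574e-02,1.196625e-03,2.159445e-03
4846.11,8.274942e-08,2.443557e-02,1.196625e-03,3.075376e-03
5374.488,5.681320e-08,2.279572e-02,1.196625e-03,3.991306e-03
5960.475,3.896159e-08,2.124421e-02,1.196625e-03,4.907237e-03
6610.354,2.668876e-08,1.977876e-02,1.196625e-03,5.823168e-03
7331.09,1.826104e-08,1.839689e-02,1.196625e-03,6.739098e-03
8130.408,1.248044e-08,1.709590e-02,1.196625e-03,7.655029e-03
9016.878,8.520062e-09,1.587293e-02,1.196625e-03,8.570960e-03
10000,5.809869e-09,1.472499e-02,1.196625e-03,9.486890e-03
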