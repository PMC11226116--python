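# synthetic photon mass attenuation table, element Na (Z=11, A=22.99)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,5.969546e+02,1.909380e-01,2.061444e+00,0.000000e+00
1.0721,4.946373e+02,1.908845e-01,2.054568e+00,0.000000e+00
1.0721,5.570012e+03,1.908845e-01,2.054568e+00,0.000000e+00
1.109031,6.468296e+03,1.908571e-01,2.050878e+00,0.000000e+00
1.229951,5.344103e+03,1.907674e-01,2.038011e+00,0.000000e+00
1.364054,4.064052e+03,1.906681e-01,2.022379e+00,0.000000e+00
1.512778,3.114562e+03,1.905581e-01,2.003439e+00,0.000000e+00
1.677719,2.383540e+03,1.904364e-01,1.980570e+00,0.000000e+00
1.860642,1.817483e+03,1.903016e-01,1.953067e+00,0.000000e+00
2.063511,1.380813e+03,1.901524e-01,1.920155e+00,0.000000e+00
2.288498,1.044500e+03,1.899873e-01,1.881002e+00,0.000000e+00
2.538016,7.874246e+02,1.898046e-01,1.834756e+00,0.000000e+00
2.814739,5.919403e+02,1.896025e-01,1.780595e+00,0.000000e+00
3.121634,4.434822e+02,1.893791e-01,1.717801e+00,0.000000e+00
3.46199,3.311727e+02,1.891321e-01,1.645857e+00,0.000000e+00
3.839456,2.467606e+02,1.888591e-01,1.564565e+00,0.000000e+00
4.258077,1.834583e+02,1.885576e-01,1.474161e+00,0.000000e+00
4.722341,1.360629e+02,1.882247e-01,1.375430e+00,0.000000e+00
5.237224,1.005949e+02,1.878573e-01,1.269768e+00,0.000000e+00
5.808245,7.424148e+01,1.874520e-01,1.159173e+00,0.000000e+00
6.441526,5.469532e+01,1.870052e-01,1.046137e+00,0.000000e+00
7.143854,4.022397e+01,1.865129e-01,9.334368e-01,0.000000e+00
7.922758,2.952903e+01,1.859709e-01,8.238551e-01,0.000000e+00
8.786587,2.163922e+01,1.853747e-01,7.198761e-01,0.000000e+00
9.744601,1.580044e+01,1.847193e-01,6.234400e-01,0.000000e+00
10.80707,1.151888e+01,1.839995e-01,5.358030e-01,0.000000e+00
11.98538,8.386654e+00,1.832098e-01,4.575292e-01,0.000000e+00
13.29216,6.098227e+00,1.823445e-01,3.885917e-01,0.000000e+00
14.74142,4.428469e+00,1.813973e-01,3.285363e-01,0.000000e+00
16.3487,3.211723e+00,1.803619e-01,2.766533e-01,0.000000e+00
18.13122,2.326252e+00,1.792319e-01,2.321194e-01,0.000000e+00
20.10809,1.682710e+00,1.780005e-01,1.940953e-01,0.000000e+00
22.3005,1.215612e+00,1.766609e-01,1.617801e-01,0.000000e+00
24.73195,8.769479e-01,1.752063e-01,1.344365e-01,0.000000e+00
27.42851,6.319741e-01,1.736303e-01,1.113973e-01,0.000000e+00
30.41908,4.549719e-01,1.719263e-01,9.206473e-02,0.000000e+00
33.73571,3.271992e-01,1.700884e-01,7.590654e-02,0.000000e+00
37.41396,2.350614e-01,1.681112e-01,6.245169e-02,0.000000e+00
41.49326,1.686907e-01,1.659901e-01,5.128626e-02,0.000000e+00
46.01732,1.209318e-01,1.637213e-01,4.204933e-02,0.000000e+00
51.03465,8.660229e-02,1.613022e-01,3.442881e-02,0.000000e+00
56.59903,6.195217e-02,1.587316e-01,2.815696e-02,0.000000e+00
62.7701,4.427123e-02,1.560096e-01,2.300589e-02,0.000000e+00
69.61401,3.160270e-02,1.531382e-01,1.878299e-02,0.000000e+00
77.20412,2.253533e-02,1.501209e-01,1.532647e-02,0.000000e+00
85.62178,1.605242e-02,1.469634e-01,1.250118e-02,0.000000e+00
94.95724,1.142230e-02,1.436730e-01,1.019475e-02,0.000000e+00
105.3106,8.119013e-03,1.402592e-01,8.314187e-03,0.000000e+00
116.7927,5.764866e-03,1.367328e-01,6.782746e-03,0.000000e+00
129.5268,4.088948e-03,1.331066e-01,5.537340e-03,0.000000e+00
143.6493,2.897146e-03,1.293945e-01,4.526241e-03,0.000000e+00
159.3115,2.050528e-03,1.256114e-01,3.707153e-03,0.000000e+00
176.6815,1.449766e-03,1.217730e-01,3.045578e-03,0.000000e+00
195.9453,1.023922e-03,1.178950e-01,2.513430e-03,0.000000e+00
217.3095,7.223928e-04,1.139932e-01,2.087870e-03,0.000000e+00
241.003,5.091170e-04,1.100828e-01,1.750302e-03,0.000000e+00
267.2799,3.584264e-04,1.061780e-01,1.485502e-03,0.000000e+00
296.4218,2.520699e-04,1.022922e-01,1.280866e-03,0.000000e+00
328.741,1.770848e-04,9.843701e-02,1.125760e-03,0.000000e+00
364.5841,1.242743e-04,9.462291e-02,1.011008e-03,0.000000e+00
404.3352,8.712075e-05,9.085874e-02,9.285423e-04,0.000000e+00
448.4204,6.101029e-05,8.715192e-02,8.712267e-04,0.000000e+00
497.3123,4.268019e-05,8.350851e-02,8.328354e-04,0.000000e+00
551.5349,2.982581e-05,7.993339e-02,8.081095e-04,0.000000e+00
611.6695,2.082099e-05,7.643045e-02,7.928126e-04,0.000000e+00
678.3607,1.451960e-05,7.300276e-02,7.837191e-04,0.000000e+00
752.3233,1.011470e-05,6.965284e-02,7.785172e-04,0.000000e+00
834.3501,7.038773e-06,6.638275e-02,7.756470e-04,0.000000e+00
925.3204,4.893141e-06,6.319432e-02,7.741150e-04,0.000000e+00
1026.209,3.398022e-06,6.008921e-02,7.733213e-04,0.000000e+00
1138.098,2.357290e-06,5.706899e-02,7.729209e-04,0.000000e+00
1262.187,1.633614e-06,5.413523e-02,7.727235e-04,0.000000e+00
1399.805,1.130931e-06,5.128944e-02,7.726280e-04,0.000000e+00
1552.427,7.821212e-07,4.853311e-02,7.725827e-04,0.000000e+00
1721.69,5.403364e-07,4.586767e-02,7.725615e-04,0.000000e+00
1909.409,3.729129e-07,4.329440e-02,7.725517e-04,0.000000e+00
2117.594,2.571015e-07,4.081444e-02,7.725472e-04,0.000000e+00
2348.478,1.770748e-07,3.842869e-02,7.725451e-04,0.000000e+00
2604.536,1.218329e-07,3.613782e-02,7.725442e-04,0.000000e+00
2888.512,8.373930e-08,3.394216e-02,7.725438e-04,0.000000e+00
3203.45,5.749783e-08,3.184173e-02,7.725436e-04,0.000000e+00
3552.727,3.943954e-08,2.983622e-02,7.725435e-04,2.114885e-04
3940.085,2.702536e-08,2.792493e-02,7.725435e-04,8.028151e-04
4369.678,1.849996e-08,2.610683e-02,7.725435e-04,1.394142e-03
4846.11,1.265118e-08,2.438055e-02,7.725434e-04,1.985468e-03
5374.488,8.642762e-09,2.274439e-02,7.725434e-04,2.576795e-03
5960.475,5.898426e-09,2.119637e-02,7.725434e-04,3.168122e-03
6610.354,4.021448e-09,1.973423e-02,7.725434e-04,3.759448e-03
7331.09,2.739000e-09,1.835547e-02,7.725434e-04,4.350775e-03
8130.408,1.863656e-09,1.705741e-02,7.725434e-04,4.942101e-03
9016.878,1.266787e-09,1.583719e-02,7.725434e-04,5.533428e-03
10000,8.602146e-10,1.469184e-02,7.725434e-04,6.124754e-03
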