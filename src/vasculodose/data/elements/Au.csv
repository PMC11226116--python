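# synthetic photon mass attenuation table, element Au (Z=79, A=196.967)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,4.444442e+03,1.600561e-01,1.261661e+01,0.000000e+00
1.109031,3.644830e+03,1.599883e-01,1.259896e+01,0.000000e+00
1.229951,2.978134e+03,1.599131e-01,1.257731e+01,0.000000e+00
1.364054,2.423031e+03,1.598299e-01,1.255077e+01,0.000000e+00
1.512778,1.957470e+03,1.597377e-01,1.251827e+01,0.000000e+00
1.677719,1.574145e+03,1.596356e-01,1.247849e+01,0.000000e+00
1.860642,1.261968e+03,1.595226e-01,1.242987e+01,0.000000e+00
2.063511,1.009255e+03,1.593976e-01,1.237053e+01,0.000000e+00
2.206,1.209760e+04,1.593099e-01,1.232551e+01,0.000000e+00
2.206,1.209648e+04,1.593099e-01,1.232551e+01,0.000000e+00
2.288498,3.029933e+03,1.592592e-01,1.229821e+01,0.000000e+00
2.291,2.936791e+03,1.592576e-01,1.229737e+01,0.000000e+00
2.291,2.936624e+03,1.592576e-01,1.229737e+01,0.000000e+00
2.538016,2.630707e+03,1.591060e-01,1.221028e+01,0.000000e+00
2.743,2.165457e+03,1.589805e-01,1.213219e+01,0.000000e+00
2.743,2.513961e+03,1.589805e-01,1.213219e+01,0.000000e+00
2.814739,2.362614e+03,1.589366e-01,1.210364e+01,0.000000e+00
3.121634,1.833926e+03,1.587493e-01,1.197471e+01,0.000000e+00
3.148,1.914278e+03,1.587333e-01,1.196314e+01,0.000000e+00
3.148,1.914268e+03,1.587333e-01,1.196313e+01,0.000000e+00
3.425,1.623359e+03,1.585648e-01,1.183690e+01,0.000000e+00
3.425,1.623351e+03,1.585648e-01,1.183690e+01,0.000000e+00
3.46199,1.582370e+03,1.585423e-01,1.181942e+01,0.000000e+00
3.839456,1.234726e+03,1.583135e-01,1.163325e+01,0.000000e+00
4.258077,9.606163e+02,1.580607e-01,1.141129e+01,0.000000e+00
4.722341,7.447456e+02,1.577817e-01,1.114842e+01,0.000000e+00
5.237224,5.757912e+02,1.574737e-01,1.083959e+01,0.000000e+00
5.808245,4.442149e+02,1.571339e-01,1.048019e+01,0.000000e+00
6.441526,3.419915e+02,1.567594e-01,1.006663e+01,0.000000e+00
7.143854,2.627532e+02,1.563467e-01,9.596935e+00,0.000000e+00
7.922758,2.015648e+02,1.558924e-01,9.071543e+00,0.000000e+00
8.786587,1.544058e+02,1.553926e-01,8.493961e+00,0.000000e+00
9.744601,1.180017e+02,1.548432e-01,7.871283e+00,0.000000e+00
10.80707,9.005216e+01,1.542398e-01,7.214304e+00,0.000000e+00
11.9187,6.968130e+01,1.536151e-01,6.573864e+00,0.000000e+00
11.9187,1.828536e+02,1.536151e-01,6.573851e+00,0.000000e+00
11.98538,1.800632e+02,1.535779e-01,6.537099e+00,0.000000e+00
13.29216,1.356908e+02,1.528525e-01,5.855964e+00,0.000000e+00
13.7336,1.241085e+02,1.526095e-01,5.642851e+00,0.000000e+00
13.7336,1.736412e+02,1.526095e-01,5.642838e+00,0.000000e+00
14.3528,1.540839e+02,1.522703e-01,5.358173e+00,0.000000e+00
14.3528,1.782487e+02,1.522703e-01,5.358161e+00,0.000000e+00
14.74142,1.665759e+02,1.520585e-01,5.187847e+00,0.000000e+00
16.3487,1.277388e+02,1.511906e-01,4.548527e+00,0.000000e+00
18.13122,9.772377e+01,1.502433e-01,3.950965e+00,0.000000e+00
20.10809,7.461190e+01,1.492111e-01,3.404214e+00,0.000000e+00
22.3005,5.686158e+01,1.480881e-01,2.913089e+00,0.000000e+00
24.73195,4.325265e+01,1.468689e-01,2.478575e+00,0.000000e+00
27.42851,3.283333e+01,1.455477e-01,2.098718e+00,0.000000e+00
30.41908,2.485535e+01,1.441193e-01,1.769674e+00,0.000000e+00
33.73571,1.879437e+01,1.425787e-01,1.486645e+00,0.000000e+00
37.41396,1.419791e+01,1.409213e-01,1.244563e+00,0.000000e+00
41.49326,1.071516e+01,1.391432e-01,1.038501e+00,0.000000e+00
46.01732,8.078620e+00,1.372414e-01,8.638768e-01,0.000000e+00
51.03465,6.084483e+00,1.352136e-01,7.165254e-01,0.000000e+00
56.59903,4.576354e+00,1.330587e-01,5.927038e-01,0.000000e+00
62.7701,3.438072e+00,1.307770e-01,4.890722e-01,0.000000e+00
69.61401,2.579671e+00,1.283699e-01,4.026687e-01,0.000000e+00
77.20412,1.934974e+00,1.258407e-01,3.308835e-01,0.000000e+00
80.7249,1.709282e+00,1.247142e-01,3.038765e-01,0.000000e+00
80.7249,8.393648e+00,1.247142e-01,3.038753e-01,0.000000e+00
85.62178,7.221462e+00,1.231939e-01,2.714350e-01,0.000000e+00
94.95724,5.527067e+00,1.204357e-01,2.223443e-01,0.000000e+00
105.3106,4.215964e+00,1.175740e-01,1.819090e-01,0.000000e+00
116.7927,3.208170e+00,1.146180e-01,1.486763e-01,0.000000e+00
129.5268,2.434060e+00,1.115782e-01,1.214152e-01,0.000000e+00
143.6493,1.845851e+00,1.084665e-01,9.908970e-02,0.000000e+00
159.3115,1.399101e+00,1.052953e-01,8.083268e-02,0.000000e+00
176.6815,1.059949e+00,1.020777e-01,6.592216e-02,0.000000e+00
195.9453,8.026030e-01,9.882691e-02,5.375957e-02,0.000000e+00
217.3095,6.074248e-01,9.555619e-02,4.385055e-02,0.000000e+00
241.003,4.594697e-01,9.227823e-02,3.578818e-02,0.000000e+00
267.2799,3.473684e-01,8.900504e-02,2.923850e-02,0.000000e+00
296.4218,2.624761e-01,8.574767e-02,2.392819e-02,0.000000e+00
328.741,1.982221e-01,8.251603e-02,1.963413e-02,0.000000e+00
364.5841,1.496149e-01,7.931881e-02,1.617457e-02,0.000000e+00
404.3352,1.128641e-01,7.616345e-02,1.340168e-02,0.000000e+00
448.4204,8.509268e-02,7.305617e-02,1.119518e-02,0.000000e+00
497.3123,6.411842e-02,7.000203e-02,9.456868e-03,0.000000e+00
551.5349,4.828653e-02,6.700515e-02,8.105812e-03,0.000000e+00
611.6695,3.634299e-02,6.406876e-02,7.074233e-03,0.000000e+00
678.3607,2.733797e-02,6.119546e-02,6.304107e-03,0.000000e+00
752.3233,2.055238e-02,5.838734e-02,5.744699e-03,0.000000e+00
834.3501,1.544217e-02,5.564616e-02,5.351140e-03,0.000000e+00
925.3204,1.159592e-02,5.297342e-02,5.084005e-03,0.000000e+00
1026.209,8.702697e-03,5.037051e-02,4.909543e-03,0.000000e+00
1138.098,6.527620e-03,4.783878e-02,4.800076e-03,0.000000e+00
1262.187,4.893389e-03,4.537952e-02,4.734092e-03,0.000000e+00
1399.805,3.666234e-03,4.299400e-02,4.695844e-03,0.000000e+00
1552.427,2.745290e-03,4.068348e-02,4.674478e-03,0.000000e+00
1721.69,2.054547e-03,3.844914e-02,4.662944e-03,0.000000e+00
1909.409,1.536761e-03,3.629206e-02,4.656908e-03,0.000000e+00
2117.594,1.148845e-03,3.421320e-02,4.653836e-03,0.000000e+00
2348.478,8.583900e-04,3.221332e-02,4.652310e-03,0.000000e+00
2604.536,6.410306e-04,3.029297e-02,4.651567e-03,0.000000e+00
2888.512,4.784615e-04,2.845243e-02,4.651212e-03,0.000000e+00
3203.45,3.569378e-04,2.669172e-02,4.651045e-03,0.000000e+00
3552.727,2.661454e-04,2.501057e-02,4.650968e-03,1.273213e-03
3940.085,1.983487e-04,2.340841e-02,4.650932e-03,4.833145e-03
4369.678,1.477499e-04,2.188437e-02,4.650916e-03,8.393078e-03
4846.11,1.100059e-04,2.043729e-02,4.650908e-03,1.195301e-02
5374.488,8.186503e-05,1.906577e-02,4.650905e-03,1.551294e-02
5960.475,6.089451e-05,1.776812e-02,4.650904e-03,1.907287e-02
6610.354,4.527496e-05,1.654246e-02,4.650903e-03,2.263281e-02
7331.09,3.364660e-05,1.538670e-02,4.650903e-03,2.619274e-02
8130.408,2.499367e-05,1.429858e-02,4.650902e-03,2.975267e-02
9016.878,1.855784e-05,1.327572e-02,4.650902e-03,3.331260e-02
10000,1.377322e-05,1.231561e-02,4.650902e-03,3.687254e-02
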