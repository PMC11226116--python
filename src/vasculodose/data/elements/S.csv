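# synthetic photon mass attenuation table, element S (Z=16, A=32.06)
# generated by scripts/make_physics_tables.py; see module docstring for models
energy_keV,photoelectric_cm2_g,incoherent_cm2_g,coherent_cm2_g,pair_cm2_g
1,2.301167e+03,1.991568e-01,3.143079e+00,0.000000e+00
1.109031,1.754064e+03,1.990724e-01,3.130470e+00,0.000000e+00
1.229951,1.334934e+03,1.989789e-01,3.115082e+00,0.000000e+00
1.364054,1.014394e+03,1.988753e-01,3.096337e+00,0.000000e+00
1.512778,7.696549e+02,1.987606e-01,3.073552e+00,0.000000e+00
1.677719,5.830863e+02,1.986336e-01,3.045930e+00,0.000000e+00
1.860642,4.410780e+02,1.984930e-01,3.012551e+00,0.000000e+00
2.063511,3.331474e+02,1.983374e-01,2.972372e+00,0.000000e+00
2.288498,2.512368e+02,1.981651e-01,2.924238e+00,0.000000e+00
2.472,2.033727e+02,1.980250e-01,2.882449e+00,0.000000e+00
2.472,2.181791e+03,1.980250e-01,2.882448e+00,0.000000e+00
2.538016,2.054749e+03,1.979746e-01,2.866902e+00,0.000000e+00
2.814739,1.578966e+03,1.977638e-01,2.799071e+00,0.000000e+00
3.121634,1.207874e+03,1.975308e-01,2.719482e+00,0.000000e+00
3.46199,9.220816e+02,1.972731e-01,2.627000e+00,0.000000e+00
3.839456,7.016822e+02,1.969884e-01,2.520766e+00,0.000000e+00
4.258077,5.323400e+02,1.966740e-01,2.400362e+00,0.000000e+00
4.722341,4.025859e+02,1.963267e-01,2.265997e+00,0.000000e+00
5.237224,3.032496e+02,1.959435e-01,2.118678e+00,0.000000e+00
5.808245,2.276723e+02,1.955207e-01,1.960329e+00,0.000000e+00
6.441526,1.705144e+02,1.950547e-01,1.793798e+00,0.000000e+00
7.143854,1.273936e+02,1.945412e-01,1.622733e+00,0.000000e+00
7.922758,9.494352e+01,1.939759e-01,1.451291e+00,0.000000e+00
8.786587,7.058458e+01,1.933540e-01,1.283730e+00,0.000000e+00
9.744601,5.231984e+01,1.926704e-01,1.123946e+00,0.000000e+00
10.80707,3.869838e+01,1.919196e-01,9.750773e-01,0.000000e+00
11.98538,2.853033e+01,1.910960e-01,8.392530e-01,0.000000e+00
13.29216,2.100205e+01,1.901933e-01,7.175375e-01,0.000000e+00
14.74142,1.543669e+01,1.892054e-01,6.100571e-01,0.000000e+00
16.3487,1.132874e+01,1.881255e-01,5.162349e-01,0.000000e+00
18.13122,8.301192e+00,1.869468e-01,4.350545e-01,0.000000e+00
20.10809,6.073359e+00,1.856624e-01,3.652881e-01,0.000000e+00
22.3005,4.436541e+00,1.842651e-01,3.056586e-01,0.000000e+00
24.73195,3.235826e+00,1.827480e-01,2.549348e-01,0.000000e+00
27.42851,2.355388e+00,1.811041e-01,2.119763e-01,0.000000e+00
30.41908,1.710310e+00,1.793267e-01,1.757490e-01,0.000000e+00
33.73571,1.240610e+00,1.774097e-01,1.453244e-01,0.000000e+00
37.41396,8.989595e-01,1.753474e-01,1.198752e-01,0.000000e+00
41.49326,6.507091e-01,1.731350e-01,9.866780e-02,0.000000e+00
46.01732,4.705143e-01,1.707686e-01,8.105696e-02,0.000000e+00
51.03465,3.398566e-01,1.682454e-01,6.647896e-02,0.000000e+00
56.59903,2.452187e-01,1.655641e-01,5.444552e-02,0.000000e+00
62.7701,1.767440e-01,1.627249e-01,4.453707e-02,0.000000e+00
69.61401,1.272529e-01,1.597299e-01,3.639594e-02,0.000000e+00
77.20412,9.152117e-02,1.565828e-01,2.971939e-02,0.000000e+00
85.62178,6.575139e-02,1.532893e-01,2.425281e-02,0.000000e+00
94.95724,4.718642e-02,1.498573e-01,1.978331e-02,0.000000e+00
105.3106,3.382651e-02,1.462965e-01,1.613372e-02,0.000000e+00
116.7927,2.422283e-02,1.426184e-01,1.315724e-02,0.000000e+00
129.5268,1.732685e-02,1.388361e-01,1.073270e-02,0.000000e+00
143.6493,1.238058e-02,1.349642e-01,8.760399e-03,0.000000e+00
159.3115,8.836674e-03,1.310183e-01,7.158556e-03,0.000000e+00
176.6815,6.300329e-03,1.270146e-01,5.860254e-03,0.000000e+00
195.9453,4.487083e-03,1.229697e-01,4.810889e-03,0.000000e+00
217.3095,3.192210e-03,1.188999e-01,3.965994e-03,0.000000e+00
241.003,2.268536e-03,1.148212e-01,3.289403e-03,0.000000e+00
267.2799,1.610375e-03,1.107484e-01,2.751685e-03,0.000000e+00
296.4218,1.141920e-03,1.066953e-01,2.328786e-03,0.000000e+00
328.741,8.088582e-04,1.026742e-01,2.000846e-03,0.000000e+00
364.5841,5.723180e-04,9.869588e-02,1.751184e-03,0.000000e+00
404.3352,4.045120e-04,9.476969e-02,1.565475e-03,0.000000e+00
448.4204,2.855978e-04,9.090331e-02,1.431160e-03,0.000000e+00
497.3123,2.014229e-04,8.710308e-02,1.337131e-03,0.000000e+00
551.5349,1.419037e-04,8.337407e-02,1.273650e-03,0.000000e+00
611.6695,9.986435e-05,7.972034e-02,1.232426e-03,0.000000e+00
678.3607,7.020368e-05,7.614511e-02,1.206710e-03,0.000000e+00
752.3233,4.929954e-05,7.265100e-02,1.191296e-03,0.000000e+00
834.3501,3.458282e-05,6.924015e-02,1.182411e-03,0.000000e+00
925.3204,2.423334e-05,6.591448e-02,1.177472e-03,0.000000e+00
1026.209,1.696300e-05,6.267571e-02,1.174819e-03,0.000000e+00
1138.098,1.186123e-05,5.952549e-02,1.173436e-03,0.000000e+00
1262.187,8.285049e-06,5.646544e-02,1.172734e-03,0.000000e+00
1399.805,5.780961e-06,5.349716e-02,1.172387e-03,0.000000e+00
1552.427,4.029450e-06,5.062219e-02,1.172219e-03,0.000000e+00
1721.69,2.805649e-06,4.784201e-02,1.172138e-03,0.000000e+00
1909.409,1.951479e-06,4.515798e-02,1.172101e-03,0.000000e+00
2117.594,1.355934e-06,4.257127e-02,1.172083e-03,0.000000e+00
2348.478,9.411489e-07,4.008283e-02,1.172075e-03,0.000000e+00
2604.536,6.525664e-07,3.769334e-02,1.172071e-03,0.000000e+00
2888.512,4.520003e-07,3.540317e-02,1.172070e-03,0.000000e+00
3203.45,3.127531e-07,3.321234e-02,1.172069e-03,0.000000e+00
3552.727,2.161796e-07,3.112050e-02,1.172069e-03,3.208610e-04
3940.085,1.492723e-07,2.912693e-02,1.172069e-03,1.217995e-03
4369.678,1.029666e-07,2.723058e-02,1.172068e-03,2.115130e-03
4846.11,7.095248e-08,2.542999e-02,1.172068e-03,3.012264e-03
5374.488,4.884208e-08,2.372341e-02,1.172068e-03,3.909398e-03
5960.475,3.358749e-08,2.210876e-02,1.172068e-03,4.806532e-03
6610.354,2.307380e-08,2.058367e-02,1.172068e-03,5.703667e-03
7331.09,1.583510e-08,1.914557e-02,1.172068e-03,6.600801e-03
8130.408,1.085635e-08,1.779163e-02,1.172068e-03,7.497935e-03
9016.878,7.435495e-09,1.651889e-02,1.172068e-03,8.395070e-03
10000,5.087463e-09,1.532424e-02,1.172068e-03,9.292204e-03
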