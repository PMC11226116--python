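# synthetic 6 MV flattening-filter-free linac spectrum
# analytic representative shape (mean ~1.3 MeV), not a measured beam
energy_keV,weight
75,7.937087e-03
125,1.224906e-02
175,1.587901e-02
225,1.890430e-02
275,2.139457e-02
325,2.341245e-02
375,2.501425e-02
425,2.625052e-02
475,2.716660e-02
525,2.780313e-02
575,2.819649e-02
625,2.837919e-02
675,2.838026e-02
725,2.822561e-02
775,2.793829e-02
825,2.753879e-02
875,2.704529e-02
925,2.647391e-02
975,2.583888e-02
1025,2.515276e-02
1075,2.442660e-02
1125,2.367008e-02
1175,2.289169e-02
1225,2.209880e-02
1275,2.129784e-02
1325,2.049434e-02
1375,1.969308e-02
1425,1.889812e-02
1475,1.811292e-02
1525,1.734039e-02
1575,1.658297e-02
1625,1.584265e-02
1675,1.512106e-02
1725,1.441946e-02
1775,1.373887e-02
1825,1.308002e-02
1875,1.244341e-02
1925,1.182937e-02
1975,1.123805e-02
2025,1.066944e-02
2075,1.012342e-02
2125,9.599770e-03
2175,9.098166e-03
2225,8.618216e-03
2275,8.159461e-03
2325,7.721395e-03
2375,7.303468e-03
2425,6.905101e-03
2475,6.525686e-03
2525,6.164603e-03
2575,5.821216e-03
2625,5.494884e-03
2675,5.184964e-03
2725,4.890814e-03
2775,4.611799e-03
2825,4.347290e-03
2875,4.096667e-03
2925,3.859326e-03
2975,3.634673e-03
3025,3.422129e-03
3075,3.221135e-03
3125,3.031144e-03
3175,2.851629e-03
3225,2.682080e-03
3275,2.522005e-03
3325,2.370932e-03
3375,2.228404e-03
3425,2.093985e-03
3475,1.967254e-03
3525,1.847811e-03
3575,1.735270e-03
3625,1.629265e-03
3675,1.529445e-03
3725,1.435475e-03
3775,1.347035e-03
3825,1.263823e-03
3875,1.185548e-03
3925,1.111936e-03
3975,1.042726e-03
4025,9.776684e-04
4075,9.165286e-04
4125,8.590830e-04
4175,8.051195e-04
4225,7.544376e-04
4275,7.068471e-04
4325,6.621680e-04
4375,6.202302e-04
4425,5.808725e-04
4475,5.439429e-04
4525,5.092976e-04
4575,4.768007e-04
4625,4.463240e-04
4675,4.177465e-04
4725,3.909541e-04
4775,3.658390e-04
4825,3.422999e-04
4875,3.202409e-04
4925,2.995719e-04
4975,2.802081e-04
5025,2.620695e-04
5075,2.450807e-04
5125,2.291710e-04
5175,2.142737e-04
5225,2.003261e-04
5275,1.872692e-04
5325,1.750477e-04
5375,1.636093e-04
5425,1.529051e-04
5475,1.428891e-04
5525,1.335180e-04
5575,1.247514e-04
5625,1.165509e-04
5675,1.088809e-04
5725,1.017078e-04
5775,9.499994e-05
5825,8.872786e-05
5875,8.286376e-05
5925,7.738163e-05
5975,7.225704e-05
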