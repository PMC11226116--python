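# synthetic 220 kVp tungsten-anode spectrum, 2 mm Al + 0.3 mm Cu filtration
# Kramers continuum + W K lines; representative, not a measured tube
energy_keV,weight
16,2.650259e-10
18,6.480174e-08
20,2.391148e-06
22,2.766396e-05
24,1.534976e-04
26,5.250092e-04
28,1.294251e-03
30,2.534036e-03
32,4.205544e-03
34,6.187921e-03
36,8.326997e-03
38,1.047638e-02
40,1.253078e-02
42,1.440619e-02
44,1.604676e-02
46,1.743401e-02
48,1.856901e-02
50,1.946536e-02
52,2.014375e-02
54,2.062813e-02
56,2.094316e-02
58,2.111261e-02
58,2.500000e-02
59.3,4.500000e-02
60,2.115853e-02
62,2.110077e-02
64,2.095687e-02
66,2.074212e-02
67.2,2.000000e-02
68,2.046967e-02
70,2.015078e-02
72,1.979501e-02
74,1.941043e-02
76,1.900380e-02
78,1.858082e-02
80,1.814621e-02
82,1.770390e-02
84,1.725715e-02
86,1.680864e-02
88,1.636057e-02
90,1.591475e-02
92,1.547261e-02
94,1.503535e-02
96,1.460388e-02
98,1.417894e-02
100,1.376111e-02
102,1.335080e-02
104,1.294833e-02
106,1.255392e-02
108,1.216770e-02
110,1.178975e-02
112,1.142008e-02
114,1.105867e-02
116,1.070545e-02
118,1.036034e-02
120,1.002321e-02
122,9.693947e-03
124,9.372391e-03
126,9.058386e-03
128,8.751767e-03
130,8.452362e-03
132,8.159995e-03
134,7.874488e-03
136,7.595663e-03
138,7.323341e-03
140,7.057345e-03
142,6.797500e-03
144,6.543633e-03
146,6.295575e-03
148,6.053159e-03
150,5.816223e-03
152,5.584608e-03
154,5.358159e-03
156,5.136726e-03
158,4.920161e-03
160,4.708323e-03
162,4.501074e-03
164,4.298280e-03
166,4.099810e-03
168,3.905540e-03
170,3.715346e-03
172,3.529113e-03
174,3.346725e-03
176,3.168072e-03
178,2.993048e-03
180,2.821550e-03
182,2.653477e-03
184,2.488734e-03
186,2.327227e-03
188,2.168866e-03
190,2.013564e-03
192,1.861237e-03
194,1.711803e-03
196,1.565184e-03
198,1.421305e-03
200,1.280090e-03
202,1.141470e-03
204,1.005376e-03
206,8.717403e-04
208,7.404996e-04
210,6.115915e-04
212,4.849557e-04
214,3.605342e-04
216,2.382705e-04
218,1.181100e-04
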