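compound_id,ic50_uM,pic50,pred_comfa,pred_comsia,is_test,binding_mode
1,0.333,6.478,6.315,6.497,1,I
2,0.245,6.611,6.490,6.289,1,I
3,2.59,5.587,5.658,5.831,0,I
4,0.121,6.917,6.968,6.950,0,I
5,0.192,6.717,6.655,6.632,0,I
6,0.210,6.678,6.512,6.299,0,I
7,0.739,6.131,6.404,6.518,1,I
8,0.492,6.308,6.322,6.275,0,I
9,0.391,6.408,6.514,6.380,0,I
10,0.197,6.706,6.438,6.717,1,I
11,0.123,6.910,6.886,7.070,0,I
12,10.2,4.991,4.982,4.940,0,I
13,4.24,5.373,5.383,5.526,0,II
14,0.72,6.143,6.107,6.065,0,II
15,1.29,5.889,6.188,6.121,0,II
16,0.92,6.036,6.006,5.838,0,II
17,3.57,5.447,5.432,5.557,0,II
18,0.859,6.066,5.884,5.788,0,II
19,1.47,5.833,5.880,5.945,0,II
20,0.364,6.439,6.382,6.622,0,II
21,0.764,6.117,6.078,6.022,0,II
22,0.283,6.548,6.566,6.361,0,II
23,2.96,5.529,5.901,5.667,1,II
24,4.161,5.381,5.429,5.388,1,III
25,3.315,5.480,5.466,5.438,0,III
26,5.185,5.285,5.288,5.176,0,III
27,3.979,5.400,5.534,5.553,1,III
28,4.666,5.331,5.304,5.395,0,III
29,0.692,6.160,6.195,6.038,0,III
30,0.816,6.088,6.089,6.095,0,III
31,1.298,5.887,5.875,5.837,1,III
32,0.701,6.154,6.105,6.271,0,III
33,1.93,5.888,5.840,5.927,0,III
34,0.891,6.050,6.117,6.130,0,III
35,16.21,4.790,4.812,4.825,0,I
36,29.58,4.529,4.513,4.531,0,I
37,10.36,4.985,4.657,5.128,1,I
38,36.09,4.443,4.464,4.405,0,II
39,20.14,4.696,4.674,4.796,0,II
40,18.96,4.722,4.747,4.769,0,II
41,9.03,5.044,5.052,5.052,0,II
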