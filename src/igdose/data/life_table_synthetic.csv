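# Synthetic sex-specific survivorship fixture, ages 0-100.
# Gompertz-Makeham hazard mu(x) = lambda + alpha*exp(beta*x):
# male lambda=0.0008, alpha=3.790474e-05, beta=0.092 (e0 ~ 76.0 y)
# female lambda=0.0005, alpha=2.217786e-05, beta=0.094 (e0 ~ 81.0 y)
# Calibrated to US-like life expectancies; NOT an official decennial table.
age,S_male,S_female
0,1.000000,1.000000
1,0.999161,0.999477
2,0.998318,0.998952
3,0.997472,0.998424
4,0.996622,0.997895
5,0.995768,0.997362
6,0.994909,0.996826
7,0.994045,0.996287
8,0.993175,0.995745
9,0.992299,0.995198
10,0.991415,0.994646
11,0.990524,0.994090
12,0.989624,0.993528
13,0.988714,0.992960
14,0.987793,0.992385
15,0.986861,0.991803
16,0.985917,0.991213
17,0.984958,0.990614
18,0.983983,0.990005
19,0.982992,0.989385
20,0.981982,0.988753
21,0.980952,0.988109
22,0.979898,0.987449
23,0.978821,0.986774
24,0.977716,0.986082
25,0.976581,0.985370
26,0.975414,0.984637
27,0.974211,0.983882
28,0.972968,0.983101
29,0.971683,0.982291
30,0.970351,0.981452
31,0.968967,0.980579
32,0.967526,0.979669
33,0.966024,0.978718
34,0.964454,0.977723
35,0.962809,0.976679
36,0.961084,0.975582
37,0.959270,0.974426
38,0.957358,0.973205
39,0.955341,0.971914
40,0.953208,0.970545
41,0.950947,0.969092
42,0.948548,0.967545
43,0.945998,0.965897
44,0.943283,0.964137
45,0.940387,0.962254
46,0.937295,0.960237
47,0.933989,0.958074
48,0.930449,0.955750
49,0.926655,0.953251
50,0.922584,0.950560
51,0.918213,0.947658
52,0.913514,0.944528
53,0.908460,0.941148
54,0.903021,0.937494
55,0.897164,0.933543
56,0.890855,0.929267
57,0.884058,0.924638
58,0.876732,0.919625
59,0.868837,0.914193
60,0.860330,0.908309
61,0.851164,0.901932
62,0.841291,0.895023
63,0.830663,0.887537
64,0.819228,0.879429
65,0.806935,0.870651
66,0.793729,0.861150
67,0.779560,0.850874
68,0.764374,0.839769
69,0.748123,0.827776
70,0.730758,0.814839
71,0.712238,0.800900
72,0.692526,0.785900
73,0.671592,0.769783
74,0.649417,0.752495
75,0.625995,0.733987
76,0.601331,0.714215
77,0.575450,0.693141
78,0.548396,0.670739
79,0.520234,0.646995
80,0.491056,0.621909
81,0.460978,0.595500
82,0.430149,0.567806
83,0.398743,0.538892
84,0.366968,0.508848
85,0.335059,0.477793
86,0.303278,0.445880
87,0.271909,0.413293
88,0.241251,0.380252
89,0.211613,0.347008
90,0.183301,0.313843
91,0.156606,0.281066
92,0.131794,0.249002
93,0.109094,0.217989
94,0.088681,0.188362
95,0.070667,0.160444
96,0.055099,0.134526
97,0.041945,0.110858
98,0.031106,0.089633
99,0.022414,0.070973
100,0.015650,0.054922
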