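age,qx
50,0.005300
51,0.005711
52,0.006154
53,0.006631
54,0.007146
55,0.007700
56,0.008269
57,0.008881
58,0.009537
59,0.010243
60,0.011000
61,0.011900
62,0.012874
63,0.013927
64,0.015067
65,0.016300
66,0.017655
67,0.019123
68,0.020713
69,0.022435
70,0.024300
71,0.026460
72,0.028812
73,0.031374
74,0.034163
75,0.037200
76,0.040767
77,0.044676
78,0.048960
79,0.053655
80,0.058800
81,0.064789
82,0.071388
83,0.078660
84,0.086672
85,0.095500
86,0.105577
87,0.116717
88,0.129033
89,0.142648
90,0.157700
91,0.171845
92,0.187258
93,0.204054
94,0.222356
95,0.242300
96,0.259286
97,0.277462
98,0.296913
99,0.317727
100,1.000000
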