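age,q_annual
70,0.020781
71,0.022828
72,0.025075
73,0.027539
74,0.030241
75,0.033205
76,0.036453
77,0.040012
78,0.043911
79,0.048180
80,0.052852
81,0.057964
82,0.063553
83,0.069661
84,0.076331
85,0.083612
86,0.091551
87,0.100203
88,0.109621
89,0.119864
90,0.130993
91,0.143068
92,0.156152
93,0.170310
94,0.185605
95,0.202099
96,0.219852
97,0.238918
98,0.259346
99,0.281178
100,1.000000
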