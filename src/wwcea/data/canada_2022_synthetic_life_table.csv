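age,q_annual
0,0.00442
1,0.00027
2,0.00019
3,0.00015
4,0.00012
5,0.00011
6,0.00010
7,0.00009
8,0.00009
9,0.00009
10,0.00010
11,0.00011
12,0.00013
13,0.00017
14,0.00022
15,0.00029
16,0.00037
17,0.00046
18,0.00056
19,0.00064
20,0.00070
21,0.00075
22,0.00078
23,0.00080
24,0.00082
25,0.00084
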