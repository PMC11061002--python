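index,delay_days
0,0.04166666667
1,0.06277743429
2,0.09458415014
3,0.1425060065
4,0.214707875
5,0.3234914283
6,0.4873910851
7,0.7343318837
8,1.106387318
9,1.666947771
10,2.5115209
11,3.784004118
12,5.701201677
13,8.589763527
14,12.94183957
15,19.49893159
16,29.37822952
17,44.26295696
18,66.68915693
19,100.47778
20,151.3856936
21,228.0865303
22,343.648492
23,517.760895
24,780.0888135
25,1175.327381
26,1770.816899
27,2668.016196
28,4019.789074
29,6056.449067
30,9125
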