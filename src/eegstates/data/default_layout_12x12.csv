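# Default 128-channel montage on a 12x12 scalp grid.
# 1-based indices; row 1 = front of head, cols 1-6 left hemisphere, 7-12 right.
# Cells (1,3) and (1,10) are reserved empty prefrontal reference positions.
# 14 doubled electrodes each occupy two vertically adjacent cells (whole back row, plus the two front corners doubled sideways).
channel_id,row,col,region
1,1,1,prefrontal
1,1,2,prefrontal
2,1,4,prefrontal
3,1,5,prefrontal
4,1,6,prefrontal
5,1,7,prefrontal
6,1,8,prefrontal
7,1,9,prefrontal
8,1,11,prefrontal
8,1,12,prefrontal
9,2,1,prefrontal
10,2,2,prefrontal
11,2,3,prefrontal
12,2,4,prefrontal
13,2,5,prefrontal
14,2,6,prefrontal
15,2,7,prefrontal
16,2,8,prefrontal
17,2,9,prefrontal
18,2,10,prefrontal
19,2,11,prefrontal
20,2,12,prefrontal
21,3,1,frontal
22,3,2,frontal
23,3,3,frontal
24,3,4,frontal
25,3,5,frontal
26,3,6,frontal
27,3,7,frontal
28,3,8,frontal
29,3,9,frontal
30,3,10,frontal
31,3,11,frontal
32,3,12,frontal
33,4,1,frontal
34,4,2,frontal
35,4,3,frontal
36,4,4,frontal
37,4,5,frontal
38,4,6,frontal
39,4,7,frontal
40,4,8,frontal
41,4,9,frontal
42,4,10,frontal
43,4,11,frontal
44,4,12,frontal
45,5,1,temporal-L
46,5,2,temporal-L
47,5,3,central
48,5,4,central
49,5,5,central
50,5,6,central
51,5,7,central
52,5,8,central
53,5,9,central
54,5,10,central
55,5,11,temporal-R
56,5,12,temporal-R
57,6,1,temporal-L
58,6,2,temporal-L
59,6,3,central
60,6,4,central
61,6,5,central
62,6,6,central
63,6,7,central
64,6,8,central
65,6,9,central
66,6,10,central
67,6,11,temporal-R
68,6,12,temporal-R
69,7,1,temporal-L
70,7,2,temporal-L
71,7,3,parietal
72,7,4,parietal
73,7,5,parietal
74,7,6,parietal
75,7,7,parietal
76,7,8,parietal
77,7,9,parietal
78,7,10,parietal
79,7,11,temporal-R
80,7,12,temporal-R
81,8,1,temporal-L
82,8,2,temporal-L
83,8,3,parietal
84,8,4,parietal
85,8,5,parietal
86,8,6,parietal
87,8,7,parietal
88,8,8,parietal
89,8,9,parietal
90,8,10,parietal
91,8,11,temporal-R
92,8,12,temporal-R
93,9,1,parietal
94,9,2,parietal
95,9,3,parietal
96,9,4,parietal
97,9,5,parietal
98,9,6,parietal
99,9,7,parietal
100,9,8,parietal
101,9,9,parietal
102,9,10,parietal
103,9,11,parietal
104,9,12,parietal
105,10,1,occipital
106,10,2,occipital
107,10,3,occipital
108,10,4,occipital
109,10,5,occipital
110,10,6,occipital
111,10,7,occipital
112,10,8,occipital
113,10,9,occipital
114,10,10,occipital
115,10,11,occipital
116,10,12,occipital
117,11,1,occipital
118,11,2,occipital
119,11,3,occipital
120,11,4,occipital
121,11,5,occipital
122,11,6,occipital
123,11,7,occipital
124,11,8,occipital
125,11,9,occipital
126,11,10,occipital
127,11,11,occipital
128,11,12,occipital
117,12,1,occipital
118,12,2,occipital
119,12,3,occipital
120,12,4,occipital
121,12,5,occipital
122,12,6,occipital
123,12,7,occipital
124,12,8,occipital
125,12,9,occipital
126,12,10,occipital
127,12,11,occipital
128,12,12,occipital
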