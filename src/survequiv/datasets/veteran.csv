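time,event,group
72,1,1
411,1,1
228,1,1
126,1,1
118,1,1
10,1,1
82,1,1
110,1,1
314,1,1
100,0,1
42,1,1
8,1,1
144,1,1
25,0,1
11,1,1
30,1,1
384,1,1
4,1,1
54,1,1
13,1,1
123,0,1
97,0,1
153,1,1
59,1,1
117,1,1
16,1,1
151,1,1
22,1,1
56,1,1
21,1,1
18,1,1
139,1,1
20,1,1
31,1,1
52,1,1
287,1,1
18,1,1
51,1,1
122,1,1
27,1,1
54,1,1
7,1,1
63,1,1
392,1,1
10,1,1
8,1,1
92,1,1
35,1,1
117,1,1
132,1,1
12,1,1
162,1,1
3,1,1
95,1,1
177,1,1
162,1,1
216,1,1
553,1,1
278,1,1
12,1,1
260,1,1
200,1,1
156,1,1
182,0,1
143,1,1
105,1,1
103,1,1
250,1,1
100,1,1
999,1,2
112,1,2
87,0,2
231,0,2
242,1,2
991,1,2
111,1,2
1,1,2
587,1,2
389,1,2
33,1,2
25,1,2
357,1,2
467,1,2
201,1,2
1,1,2
30,1,2
44,1,2
283,1,2
15,1,2
25,1,2
103,0,2
21,1,2
13,1,2
87,1,2
2,1,2
20,1,2
7,1,2
24,1,2
99,1,2
8,1,2
99,1,2
61,1,2
25,1,2
95,1,2
80,1,2
51,1,2
29,1,2
24,1,2
18,1,2
83,0,2
31,1,2
51,1,2
90,1,2
52,1,2
73,1,2
8,1,2
36,1,2
48,1,2
7,1,2
140,1,2
186,1,2
84,1,2
19,1,2
45,1,2
80,1,2
52,1,2
164,1,2
19,1,2
53,1,2
15,1,2
43,1,2
340,1,2
133,1,2
111,1,2
231,1,2
378,1,2
49,1,2
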