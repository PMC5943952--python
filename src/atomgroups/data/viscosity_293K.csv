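entry,atom_type,neighbors,contribution,occurrences,molecules,valid
1,Const,,-0.70,501,501,1
2,B(-),F4,1.50,4,4,1
3,C sp3,H3C,-0.06,694,389,1
4,C sp3,H3C(+),2.07,3,3,1
5,C sp3,H3N,0.54,31,21,1
6,C sp3,H3N(+),0.69,2,2,0
7,C sp3,H3O,0.43,31,25,1
8,C sp3,H3S,0.19,7,5,1
9,C sp3,H3Si,0.13,18,2,0
10,C sp3,H2C2,0.09,1634,313,1
11,C sp3,H2CN,0.63,87,51,1
12,C sp3,H2CN(+),1.75,13,12,1
13,C sp3,H2CO,0.51,182,118,1
14,C sp3,H2CP(+),0.43,12,3,1
15,C sp3,H2CS,0.36,20,15,1
16,C sp3,H2CCl,0.33,23,20,1
17,C sp3,H2CBr,0.44,14,12,1
18,C sp3,H2CJ,0.59,3,3,1
19,C sp3,H2O2,0.93,1,1,0
20,C sp3,HC3,0.21,118,92,1
21,C sp3,HC2N,0.65,8,7,1
22,C sp3,HC2N(+),0.89,1,1,0
23,C sp3,HC2O,0.69,17,16,1
24,C sp3,H2CP,0.08,2,1,0
25,C sp3,HC2S,0.50,4,4,1
26,C sp3,HC2Cl,0.41,5,5,1
27,C sp3,HC2Br,0.58,1,1,0
28,C sp3,HC2J,0.67,1,1,0
29,C sp3,HCO2,1.11,3,1,0
30,C sp3,HCF2,1.49,1,1,0
31,C sp3,HCCl2,0.37,3,3,1
32,C sp3,HCBr2,0.85,2,1,0
33,C sp3,C4,0.44,14,10,1
34,C sp3,C3O,0.89,6,6,1
35,C sp3,C3S,0.72,3,3,1
36,C sp3,C3Cl,0.60,1,1,0
37,C sp3,C3J,0.83,1,1,0
38,C sp3,C2O2,1.14,1,1,0
39,C sp3,CSF2,0.00,1,1,0
40,C sp3,CPF2(-),0.19,6,2,0
41,C sp3,CF3,-0.15,10,6,1
42,C sp3,CF2Cl,0.55,1,1,0
43,C sp3,CFCl2,0.00,1,1,0
44,C sp3,CCl3,0.72,1,1,0
45,C sp3,SF3,0.43,14,7,1
46,C sp2,H2=C,-0.06,42,40,1
47,C sp2,HC=C,0.05,74,52,1
48,C sp2,HC=O,0.26,7,7,1
49,C sp2,H=CN,0.48,28,14,1
50,C sp2,H=CO,-0.01,6,5,1
51,C sp2,H=CS,0.26,5,3,1
52,C sp2,H=CCl,0.17,5,3,1
53,C sp2,HN=O,0.51,3,3,1
54,C sp2,HO=O,0.12,9,9,1
55,C sp2,C2=C,0.13,11,11,1
56,C sp2,C2=O,0.37,15,14,1
57,C sp2,C=CS,0.35,1,1,0
58,C sp2,CN=O,0.66,4,4,1
59,C sp2,CN=O(+),-3.99,1,1,0
60,C sp2,CO=O,0.26,100,83,1
61,C sp2,CO=O(-),0.95,3,3,1
62,C sp2,C=OBr,0.44,1,1,0
63,C sp2,=CCl2,0.32,4,3,1
64,C sp2,O2=O,0.29,3,3,1
65,C aromatic,H:C2,0.07,441,97,1
66,C aromatic,H:C:N,0.24,7,4,1
67,C aromatic,H:C:N(+),0.00,18,9,1
68,C aromatic,:C3,0.31,4,2,0
69,C aromatic,C:C2,0.20,90,73,1
70,C aromatic,C:C:N,0.40,3,2,0
71,C aromatic,:C2N,0.28,9,9,1
72,C aromatic,:C2N(+),0.83,3,3,1
73,C aromatic,:C2O,0.22,9,6,1
74,C aromatic,:C2S,1.42,3,3,1
75,C aromatic,:C2F,0.09,4,4,1
76,C aromatic,:C2Cl,0.25,6,4,1
77,C aromatic,:C2Br,0.36,2,2,0
78,C aromatic,:C2J,0.57,1,1,0
79,C(+) aromatic,H:N2,0.40,10,10,1
80,C(+) aromatic,C:N2,-3.06,3,3,1
81,C sp,H#C,-0.17,1,1,0
82,C sp,C#C,0.00,1,1,0
83,C sp,C#N,0.35,19,19,1
84,C sp,N#N(-),-0.02,2,1,0
85,C sp,#NS(-),1.59,1,1,0
86,N sp3,H2C,-0.21,19,18,1
87,N sp3,H2C(pi),0.66,7,7,1
88,N sp3,HC2,-0.74,12,12,1
89,N sp3,HC2(pi),0.02,3,3,1
90,N sp3,HC2(2pi),-0.23,1,1,0
91,N sp3,C3,-1.38,12,12,1
92,N sp3,C3(pi),-0.92,6,6,1
93,N sp3,C2P,-0.66,3,1,0
94,N(+) sp3,H3C,0.14,2,2,0
95,N(+) sp3,C4,-0.95,1,1,0
96,N aromatic,:C2,-0.12,5,5,1
97,N aromatic,C2:C(+),-0.05,26,13,1
98,N(+) aromatic,C:C2,-0.54,9,9,1
99,N(+) sp2,CO=O(-),-0.18,5,5,1
100,N(+) sp2,O2=O(-),0.74,1,1,0
101,N(-),C2,0.00,1,1,0
102,N(-),S2,0.86,7,7,1
103,O,HC,0.58,58,45,1
104,O,HC(pi),0.63,18,18,1
105,O,C2,-0.79,40,31,1
106,O,C2(pi),-0.25,97,80,1
107,O,C2(2pi),0.20,6,6,1
108,O,CP,-0.13,9,3,1
109,O,CP(pi),0.29,3,1,0
110,O,CS,-0.06,2,2,0
111,O,Si2,0.00,9,2,0
112,P4,C2O=O(-),-0.88,1,1,0
113,P4,N3=O,0.00,1,1,0
114,P4,O3=O,0.00,4,4,1
115,P(+),C4,-0.22,3,3,1
116,P(-),F6,0.84,2,2,0
117,P(-),C3F3,-0.07,2,2,0
118,S2,HC,-0.09,13,13,1
119,S2,HC(pi),-0.98,1,1,0
120,S2,C2,-0.21,9,9,1
121,S2,C2(2pi),-0.10,3,3,1
122,S4,C2=O,0.67,1,1,0
123,S4,CN=O2(-),0.00,14,7,1
124,S4,CO=O2(-),-1.08,4,4,1
125,S4,O2=O2(-),0.00,2,2,0
126,Si,C2O2,0.00,9,2,0
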