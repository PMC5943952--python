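entry,atom_type,neighbors,contribution,occurrences,molecules,valid
1,C sp3,H3C,0.99,776,422,1
2,C sp3,H3N,0.91,27,20,1
3,C sp3,H3N(+),0.38,1,1,0
4,C sp3,H3O,0.86,50,45,1
5,C sp3,H3S,1.20,9,6,1
6,C sp3,H2C2,0.60,972,284,1
7,C sp3,H2CN,0.27,52,29,1
8,C sp3,H2CN(+),0.80,3,3,1
9,C sp3,H2CO,0.21,131,101,1
10,C sp3,H2CS,0.19,9,6,1
11,C sp3,H2CF,0.70,1,1,0
12,C sp3,H2CCl,1.41,23,19,1
13,C sp3,H2CBr,1.81,15,13,1
14,C sp3,H2CJ,2.45,5,5,1
15,C sp3,HC3,0.14,96,71,1
16,C sp3,HC2N,0.28,6,6,1
17,C sp3,HC2N(+),0.37,1,1,0
18,C sp3,HC2O,-0.39,52,49,1
19,C sp3,HC2S,-0.14,3,2,0
20,C sp3,HC2Cl,1.02,4,4,1
21,C sp3,HC2Br,1.25,3,3,1
22,C sp3,HC2J,1.85,1,1,0
23,C sp3,HCCl2,1.79,7,6,1
24,C sp3,HCBr2,2.23,2,1,0
25,C sp3,C4,-0.46,37,33,1
26,C sp3,C3O,-1.14,21,20,1
27,C sp3,C3F,1.29,1,1,0
28,C sp3,C2F2,1.12,18,4,1
29,C sp3,CF3,1.82,10,6,1
30,C sp3,CF2Cl,2.43,4,3,1
31,C sp3,CFCl2,2.19,1,1,0
32,C sp3,CCl3,2.76,5,4,1
33,C sp2,H2=C,0.98,54,45,1
34,C sp2,HC=C,0.60,109,69,1
35,C sp2,HC=O,-0.30,17,17,1
36,C sp2,H=CN,0.90,6,4,1
37,C sp2,H=CO,0.88,8,6,1
38,C sp2,H=CS,-0.99,3,3,1
39,C sp2,H=CCl,1.54,7,5,1
40,C sp2,HN=O,-0.70,2,2,0
41,C sp2,HO=O,0.84,8,8,1
42,C sp2,C2=C,0.24,15,15,1
43,C sp2,C2=N,1.59,2,2,0
44,C sp2,C=CN,-2.47,1,1,0
45,C sp2,C2=O,-1.17,38,35,1
46,C sp2,C=CO,0.54,7,5,1
47,C sp2,C=CS,0.09,1,1,0
48,C sp2,CN=O,-0.23,34,25,1
49,C sp2,CO=O,0.06,91,83,1
50,C sp2,=CF2,1.51,2,1,0
51,C sp2,=CCl2,2.30,3,2,0
52,C sp2,N2=N,0.40,1,1,0
53,C sp2,N2=O,0.41,15,15,1
54,C sp2,N=NS,-0.04,2,2,0
55,C sp2,O2=O,0.88,2,2,0
56,C aromatic,H:C2,0.56,1318,270,1
57,C aromatic,H:C:N,-0.39,25,17,1
58,C aromatic,:C3,0.16,92,27,1
59,C aromatic,C:C2,0.06,209,138,1
60,C aromatic,C:C:N,-1.04,10,8,1
61,C aromatic,:C2N,-0.65,90,65,1
62,C aromatic,:C2N(+),0.56,43,33,1
63,C aromatic,:C2O,0.13,67,58,1
64,C aromatic,:C2S,0.34,42,40,1
65,C aromatic,:C2F,0.72,22,8,1
66,C aromatic,:C2Cl,1.26,108,59,1
67,C aromatic,:C2Br,1.50,30,16,1
68,C aromatic,:C2J,1.88,6,5,1
69,C aromatic,:CN:N,-0.66,3,3,1
70,C aromatic,:C:NCl,1.22,2,2,0
71,C aromatic,N:N2,0.14,4,3,1
72,C aromatic,:N2Cl,-0.74,1,1,0
73,C sp,H#C,0.69,13,10,1
74,C sp,C#C,0.22,11,9,1
75,C sp,C#N,-0.07,10,10,1
76,C sp,N#N,0.00,1,1,0
77,C sp,=N=S,3.15,1,1,0
78,N sp3,H2C,-1.57,10,10,1
79,N sp3,H2C(pi),0.16,38,37,1
80,N sp3,HC2,-1.62,6,6,1
81,N sp3,HC2(pi),-0.11,6,5,1
82,N sp3,HC2(2pi),-0.95,37,28,1
83,N sp3,HCS,-0.59,1,1,0
84,N sp3,HCS(pi),-1.13,32,32,1
85,N sp3,C3,-1.62,10,9,1
86,N sp3,C3(pi),-1.48,6,6,1
87,N sp3,C3(2pi),-1.59,4,4,1
88,N sp3,C2N(pi),-1.91,1,1,0
89,N sp3,C2N(2pi),0.00,1,1,0
90,N sp3,C2O(pi),-0.33,2,2,0
91,N sp3,C2S,-0.97,2,2,0
92,N sp3,C2S(2pi),-2.06,1,1,0
93,N sp2,H=C,0.79,1,1,0
94,N sp2,C=C,-1.63,5,5,1
95,N sp2,C=N,0.21,2,1,0
96,N aromatic,:C2,0.31,24,20,1
97,N aromatic,:C:N,-0.16,2,1,0
98,N(+) sp2,CO=O(-),0.12,48,38,1
99,O,HC,-0.84,81,77,1
100,O,HC(pi),-0.90,67,63,1
101,O,HO,-0.39,3,2,0
102,O,C2,-0.37,36,34,1
103,O,C2(pi),-0.41,96,84,1
104,O,C2(2pi),-0.61,11,11,1
105,O,CN,0.00,2,2,0
106,O,CO,-0.15,3,2,0
107,S2,HC,1.12,7,6,1
108,S2,C2,0.29,3,3,1
109,S2,C2(2pi),2.31,5,5,1
110,S2,CS,0.42,2,1,0
111,S4,C2=O,-4.04,2,2,0
112,S4,C2=O2,-1.81,2,2,0
113,S4,CN=O2,-0.07,36,36,1
114,H,H Acceptor,0.14,6,6,1
115,Alkane,No of C atoms,0.19,272,39,1
116,Unsaturated HC,No of C atoms,0.03,844,92,1
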