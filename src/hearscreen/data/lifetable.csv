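age,qx
0,0.005
1,0.0003220736559762516
2,0.00032442432320667347
3,0.0003270248050165625
4,0.00032990164941881783
5,0.0003330842255374611
6,0.0003366050233536422
7,0.0003404999852911761
8,0.00034480887302235086
9,0.0003495756732327937
10,0.00035484904647953286
11,0.0003606828237157078
12,0.0003671365555408812
13,0.00037427611976803554
14,0.00038217439349597093
15,0.00039091199652452335
16,0.00040057811367855134
17,0.00041127140440377907
18,0.00042310100888254265
19,0.0004361876608934834
20,0.0004506649187185907
21,0.0004666805265942653
22,0.00048439792051813146
23,0.0005039978936782763
24,0.0005256804383789726
25,0.0005496667831055291
26,0.0005762016453333407
27,0.0006055557228388242
28,0.000638028448656236
29,0.0006739510374469404
30,0.0007136898539457093
31,0.0007576501373357525
32,0.0008062801189204771
33,0.0008600755743257693
34,0.0009195848557261854
35,0.0009854144542658094
36,0.0010582351479920815
37,0.0011387887962654997
38,0.0012278958478106894
39,0.0013264636363615745
40,0.0014354955452995366
41,0.0015561011308108386
42,0.0016895073019835838
43,0.0018370706659466274
44,0.0020002911567085224
45,0.0021808270778089778
46,0.0023805117013245836
47,0.0026013715792005954
48,0.00284564673736043
49,0.0031158129386023026
50,0.0034146062169326807
51,0.0037450499037107177
52,0.004110484384742263
53,0.004514599847194933
54,0.004961472295796132
55,0.005455603139027043
56,0.006001962667701144
57,0.00660603777003943
58,0.007273884248677587
59,0.008012184125312016
60,0.008828308337119561
61,0.009730385244619888
62,0.010727375381965887
63,0.011829152886086325
64,0.013046594038570003
65,0.014391673341100697
66,0.01587756751841307
67,0.01751876779823669
68,0.019331200750746236
69,0.02133235787482879
70,0.023541433988049865
71,0.025979474303148176
72,0.028669529846271358
73,0.03163682057918793
74,0.03490890521558887
75,0.03851585625428611
76,0.04249043817121967
77,0.04686828599681303
78,0.05168808063204988
79,0.056991716200146536
80,0.06282445346363108
81,0.06923505183095513
82,0.07627587070506703
83,0.0840029288641101
84,0.09247590819310691
85,0.10175808539724729
86,0.11191617233106144
87,0.12302004230718977
88,0.13514231627318896
89,0.1483577791837487
90,0.16274259343382513
91,0.17837327312683837
92,0.19532538061182525
93,0.2136719056494617
94,0.23348128843387828
95,0.25481505136135385
96,0.27772501194821175
97,0.30225006189769166
98,0.3284125163931245
99,0.35621406472225225
100,0.38563138971710686
101,0.4166115703293969
102,0.4490674394190425
103,0.48287313687525146
104,0.5178601741778928
105,0.5538144057048081
106,0.5904743766296525
107,0.6275315755097837
108,0.6646331459666905
109,0.7013875868840218
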