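age,male,female
20,0.0027803492214392429,0.0027803492214392429
21,0.0029648698005757517,0.0029648698005757517
22,0.0031604350646021948,0.0031604350646021948
23,0.0033675439598742493,0.0033675439598742493
24,0.0035866961705434065,0.0035866961705434065
25,0.0038183887418464534,0.0038183887418464534
26,0.0040631122724148188,0.0040631122724148188
27,0.0043213466647828401,0.0043213466647828401
28,0.0045935564303483164,0.0045935564303483164
29,0.004880185553657752,0.004880185553657752
30,0.0051816519311091314,0.0051816519311091314
31,0.0054983414109908459,0.0054983414109908459
32,0.0058306014751410883,0.0058306014751410883
33,0.0061787346172690856,0.0061787346172690856
34,0.0065429914888816216,0.0065429914888816216
35,0.0069235639004496382,0.0069235639004496382
36,0.0073205777824572162,0.0073205777824572162
37,0.0077340862277065726,0.0077340862277065726
38,0.0081640627520010011,0.0081640627520010011
39,0.0086103949242868176,0.0086103949242868176
40,0.0090728785286246106,0.0090728785286246106
41,0.0095512124280604672,0.0095512124280604672
42,0.010044994303670143,0.010044994303670143
43,0.010553717439911143,0.010553717439911143
44,0.011076768719228953,0.011076768719228953
45,0.011613427974114188,0.011613427974114188
46,0.012162868823253944,0.012162868823253944
47,0.012724161090145179,0.012724161090145179
48,0.013296274867991845,0.013296274867991845
49,0.01387808625473458,0.01387808625473458
50,0.01446838473789345,0.01446838473789345
51,0.015065882162126985,0.015065882162126985
52,0.015669223164898619,0.015669223164898619
53,0.016276996919462494,0.016276996919462494
54,0.016887749981676362,0.016887749981676362
55,0.017500000000000002,0.017500000000000002
56,0.018112250018323641,0.018112250018323641
57,0.018723003080537509,0.018723003080537509
58,0.019330776835101388,0.019330776835101388
59,0.019934117837873019,0.019934117837873019
60,0.020531615262106555,0.020531615262106555
61,0.021121913745265421,0.021121913745265421
62,0.021703725132008158,0.021703725132008158
63,0.022275838909854826,0.022275838909854826
64,0.022837131176746059,0.022837131176746059
65,0.023386572025885819,0.023386572025885819
66,0.023923231280771048,0.023923231280771048
67,0.02444628256008886,0.02444628256008886
68,0.024955005696329861,0.024955005696329861
69,0.025448787571939538,0.025448787571939538
70,0.025927121471375394,0.025927121471375394
71,0.026389605075713189,0.026389605075713189
72,0.026835937247998997,0.026835937247998997
73,0.027265913772293433,0.027265913772293433
74,0.027679422217542788,0.027679422217542788
75,0.028076436099550368,0.028076436099550368
76,0.028457008511118379,0.028457008511118379
77,0.028821265382730919,0.028821265382730919
78,0.029169398524858916,0.029169398524858916
79,0.029501658589009161,0.029501658589009161
80,0.029818348068890874,0.029818348068890874
81,0.030119814446342253,0.030119814446342253
82,0.030406443569651689,0.030406443569651689
83,0.030678653335217163,0.030678653335217163
84,0.030936887727585186,0.030936887727585186
85,0.031181611258153552,0.031181611258153552
86,0.031413303829456597,0.031413303829456597
87,0.031632456040125753,0.031632456040125753
88,0.031839564935397809,0.031839564935397809
89,0.03203513019942425,0.03203513019942425
90,0.03221965077856076,0.03221965077856076
91,0.032393621919189021,0.032393621919189021
92,0.032557532599319698,0.032557532599319698
93,0.032711863330104958,0.032711863330104958
94,0.032857084301303227,0.032857084301303227
95,0.032993653843539597,0.032993653843539597
96,0.033122017179748983,0.033122017179748983
97,0.033242605438340678,0.033242605438340678
98,0.033355834901260074,0.033355834901260074
99,0.033462106461135059,0.033462106461135059
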