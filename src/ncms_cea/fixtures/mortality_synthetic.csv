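age,male,female
20,0.0004776781710993383,0.00028663428993735973
21,0.00051406600578685069,0.00030847132274502975
22,0.00055395882535091978,0.00033241212917900498
23,0.00059769407957221965,0.00035865932829026725
24,0.00064564167443037501,0.00038743504211635749
25,0.00069820708720402802,0.0004189827705676219
26,0.00075583477922747111,0.00045356944607377603
27,0.00081901193447553311,0.00049148768513140872
28,0.0008882725547642023,0.00053305825550409303
29,0.00096420194519342139,0.00057863277959069315
30,0.0010474416265526809,0.00062859669640169535
31,0.0011386947147714599,0.00068337250667960259
32,0.0012387318111422019,0.00074342332798815747
33,0.0013483974510017926,0.00080925678908549958
34,0.00146861716284441,0.00088142929561141337
35,0.0016004051944739084,0.00096055070206979565
36,0.0017448729678175567,0.001047289428298015
37,0.0019032383294211863,0.0011423780621021562
38,0.002076835669469923,0.0012466194935183417
39,0.0022671269884197986,0.001360893630267368
40,0.0024757139970309483,0.0014861647484049056
41,0.0027043513427454924,0.0016234895369757751
42,0.0029549610629838741,0.0017740259006616688
43,0.0032296483740279491,0.0019390425900015495
44,0.0035307189127203875,0.0021199297347671564
45,0.0038606975572124114,0.0023182103625308814
46,0.0042223489624114707,0.0025355529913611008
47,0.0046186999555574149,0.0027737853929492573
48,0.005053063947429659,0.0030349096303121659
49,0.0055290675249511922,0.0033211184825172602
50,0.0060506794012787912,0.0036348133776402669
51,0.0066222419096780838,0.0039786239643605503
52,0.0072485052373524317,0.0043554294621844791
53,0.0079346646046362102,0.0047683819402110084
54,0.0086864006032184582,0.0052209316845232001
55,0.0095099229138752017,0.0057168548246018247
56,0.0104120176290039,0.0062602833994523932
57,0.01140009840737255,0.0068557380542265678
58,0.012482261687078999,0.0075081635677495262
59,0.013667346176734707,0.0082229674202121128
60,0.014964996833088273,0.0090060616179612474
61,0.016385733514189482,0.009863907998315824
62,0.01794102446896173,0.010803567241037704
63,0.019643364784540651,0.011832751813740328
64,0.021506359859402413,0.012959883075195799
65,0.023544813900114425,0.014194152752083911
66,0.02577482334894643,0.015545588989857251
67,0.028213875034421632,0.017025127155442576
68,0.030880948692346588,0.018644685536503003
69,0.033796623325350716,0.020417246036634862
70,0.036983186648131383,0.02235693990539056
71,0.040464746596187817,0.024479138463169403
72,0.044267343549723726,0.026800548679978942
73,0.048419061532588792,0.029339313339391992
74,0.052950136178788743,0.032115115359568347
75,0.057893056705691781,0.035149285646030703
76,0.063282658482626264,0.038464913609253526
77,0.069156202025035696,0.042086959186377171
78,0.075553433367207545,0.046042364852007078
79,0.082516619761566656,0.050360165678682955
80,0.090090553512902072,0.055071595003065021
81,0.098322515478939332,0.060210182658400169
82,0.10726218835776824,0.065811842036349821
83,0.11696150834996399,0.071914941430853752
84,0.1274744421531685,0.078560354183311976
85,0.13885667456029926,0.085791481083698162
86,0.15116519025199371,0.09365423728110589
87,0.16445773178982426,0.10219699461940357
88,0.17879211445477605,0.11147046884606859
89,0.19422537760398939,0.1215275395620572
90,0.21081275185777049,0.13242298911891615
91,0.22860642195780734,0.14421314497613602
92,0.24765406690211555,0.15695540838119815
93,0.26799716237838178,0.17070765073212013
94,0.2896690360694445,0.18552745777129087
95,0.31269267463564066,0.20147120103053273
96,0.33707829266726552,0.21859291594625396
97,0.36282068921996824,0.23694296709865414
98,0.38989643720047262,0.2565664834771717
99,0.41826097519884986,0.27750155098286222
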