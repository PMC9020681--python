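age,qx
50,0.0025606408606969155
51,0.0027885281078571574
52,0.0030415838603814627
53,0.003322580296463799
54,0.0036345931827956573
55,0.003981034711601809
56,0.0043656897933194065
57,0.00479275614584742
58,0.005266888549437271
59,0.005793247665359965
60,0.0063775538460777445
61,0.007026146394222701
62,0.007746048756503427
63,0.008545040165742366
64,0.009431734268310952
65,0.010415665293619994
66,0.01150738233492398
67,0.012718552313825938
68,0.014062072191150608
69,0.015552190960073934
70,0.01720464190832694
71,0.019036785558487715
72,0.02106776358093736
73,0.023318663813372824
74,0.025812696302210895
75,0.02857537999082232
76,0.03163473930065487
77,0.03502150936427425
78,0.03876934805114719
79,0.042915052150975616
80,0.0474987741151479
81,0.05256423457025217
82,0.05815892437104962
83,0.06433428821368052
84,0.0711458797418898
85,0.0786534756096564
86,0.08692113307767657
87,0.09601717239384717
88,0.10601406143234114
89,0.1169881758636053
90,0.12901940356275063
91,0.14219055716136594
92,0.15658655381712352
93,0.17229331673904077
94,0.18939634923349244
95,0.20797892968217965
96,0.22811987580948398
97,0.2498908299879039
98,0.2733530256025407
99,0.2985535093800497
100,0.32552081807412786
101,0.3542601421354666
102,0.38474805608409746
103,0.41692695697588916
104,0.45069942946024777
105,0.485922847717019
106,0.5224046277722881
107,0.5598986514400891
108,0.5981034837550286
109,0.6366630818265375
110,0.6751707209783997
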