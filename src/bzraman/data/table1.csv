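structure,fragment,delta_e_kcal,ni,hb_count,nh3_hbond_e,acoo_hbond_e,qt_weighted_e,amide_I_band,acoo_band
EG-A,EG,0.00,9.74e-1,2,0.360,0.234,5.94e-1,1655,1645
EG-B,EG,2.39,1.73e-2,2,0.006,0.003,9.70e-3,-4,0
EG-C,EG,3.03,5.94e-3,3,0.002,0.002,5.28e-3,29,-6
EG-D,EG,3.65,2.06e-3,3,0.001,0.001,1.85e-3,26,-13
EG-E,EG,4.04,1.07e-3,2,0.000,0.000,6.71e-4,-3,-1
EG-F,EG,8.91,2.83e-7,2,0.000,0.000,1.98e-7,43,81
ED-A,ED,0.00,9.99e-1,3,0.270,0.250,8.49e-1,1631,1609
ED-B,ED,4.06,1.04e-3,3,0.000,0.000,7.60e-4,34,138
ED-C,ED,4.95,2.33e-4,4,0.000,0.000,1.72e-4,38,146
ED-D,ED,7.03,6.94e-6,3,0.000,0.000,5.83e-6,21,-1
ED-E,ED,9.45,1.16e-7,3,0.000,0.000,1.03e-7,37,4
ED-F,ED,9.69,7.81e-8,3,0.000,0.000,6.64e-8,39,3
EA-A,EA,0.00,9.71e-1,3,0.359,0.243,7.09e-1,1651,1642
EA-B,EA,2.13,2.64e-2,2,0.010,0.007,1.63e-2,-2,0
EA-C,EA,3.49,2.66e-3,3,0.001,0.001,2.34e-3,28,-14
EA-D,EA,7.08,6.24e-6,3,0.000,0.000,3.68e-6,2,116
EA-E,EA,12.27,9.63e-10,3,0.000,0.000,8.09e-10,29,125
EA-F,EA,24.01,2.35e-18,1,0.000,,9.15e-19,61,92
EGE-A,EGE,0.00,1.00,4,0.290,0.240,1.03,1617,1641
EGE-B,EGE,10.13,3.70e-8,2,0.000,0.000,2.30e-8,9,44
EGE-C,EGE,16.59,6.73e-13,4,0.000,0.000,6.19e-13,47,-13
EGE-D,EGE,17.14,2.67e-13,4,0.000,0.000,2.43e-13,38,-15
EGE-E,EGE,19.73,3.33e-15,4,0.000,0.000,2.99e-15,50,-18
EGE-F,EGE,24.09,2.10e-18,4,0.000,0.000,2.23e-18,85,-11
EDE-A,EDE,0.00,9.97e-1,4,0.279,0.249,9.87e-1,1634,1609
EDE-B,EDE,3.64,2.14e-3,4,0.001,0.001,2.25e-3,-9,4
EDE-C,EDE,4.46,5.31e-4,5,0.000,0.000,6.68e-4,4,-2
EDE-D,EDE,5.03,2.02e-4,5,0.000,0.000,2.36e-4,3,-2
EDE-E,EDE,7.89,1.62e-6,3,0.000,0.000,1.47e-6,24,-2
EDE-F,EDE,12.00,1.57e-9,3,0.000,0.000,1.45e-9,1,-2
DEA-A,DEA,0.00,9.99e-1,5,0.399,0.240,1.22,1635,1618
DEA-B,DEA,4.16,8.79e-4,3,0.000,0.000,8.27e-4,8,4
DEA-C,DEA,4.54,4.69e-4,4,0.000,0.000,4.60e-4,-2,10
DEA-D,DEA,6.60,1.43e-5,4,0.000,0.000,1.54e-5,-21,6
DEA-E,DEA,7.89,1.62e-6,3,0.000,0.000,1.15e-6,28,8
DEA-F,DEA,13.89,6.39e-11,3,0.000,0.000,5.75e-11,-14,-1
EGED-A,EGED,0.00,9.88e-1,4,0.385,0.227,1.01,1676,1620
EGED-B,EGED,3.02,6.04e-3,3,0.002,0.001,3.51e-3,-1,30
EGED-C,EGED,3.44,2.93e-3,4,0.001,0.001,2.49e-3,-16,11
EGED-D,EGED,3.71,1.87e-3,4,0.001,0.000,1.48e-3,4,13
EGED-E,EGED,4.29,7.09e-4,4,0.000,0.000,6.31e-4,-7,13
EGED-F,EGED,4.68,3.66e-4,2,0.000,,2.20e-4,1,107
EDEA-A,EDEA,0.00,9.29e-1,7,0.260,0.223,1.34,1639,1604
EDEA-B,EDEA,1.53,7.05e-2,6,0.022,0.016,1.05e-1,13,2
EDEA-C,EDEA,7.87,1.55e-6,5,0.000,0.000,1.91e-6,3,8
EDEA-D,EDEA,16.11,1.41e-12,5,0.000,0.000,1.79e-12,32,-3
EDEA-E,EDEA,34.60,3.84e-26,6,0.000,0.000,5.42e-26,69,11
EDEA-F,EDEA,47.14,2.40e-35,5,0.000,,2.96e-35,100,5
EGEDE-A,EGEDE,0.00,1.00,6,0.380,0.230,1.24,1650,1614
EGEDE-B,EGEDE,4.52,4.83e-4,5,0.000,0.000,4.49e-4,9,11
EGEDE-C,EGEDE,8.65,4.51e-7,5,0.000,0.000,4.29e-7,32,-5
EGEDE-D,EGEDE,11.67,2.72e-9,6,0.000,0.000,3.40e-9,2,83
EGEDE-E,EGEDE,11.70,2.62e-9,6,0.000,0.000,3.77e-9,8,-21
EGEDE-F,EGEDE,32.43,1.59e-24,6,0.000,0.000,2.28e-24,48,-9
GEDEA-A,GEDEA,0.00,1.00,6,0.380,0.230,1.53,1654,1607
GEDEA-B,GEDEA,5.92,4.55e-5,4,0.000,0.000,5.60e-5,7,3
GEDEA-C,GEDEA,11.41,4.23e-9,5,0.000,0.000,4.40e-9,19,11
GEDEA-D,GEDEA,11.47,3.86e-9,6,0.000,0.000,4.86e-9,18,-2
GEDEA-E,GEDEA,21.81,9.90e-17,4,0.000,,9.11e-17,15,106
GEDEA-F,GEDEA,27.11,1.28e-20,6,0.000,0.000,1.42e-20,52,29
EGEDEA-A,EGEDEA,0.00,9.20e-1,7,0.368,0.221,1.51,1658,1610
EGEDEA-B,EGEDEA,1.44,8.02e-2,7,0.033,0.019,1.41e-1,-1,1
EGEDEA-C,EGEDEA,11.19,5.70e-9,6,0.000,0.000,8.84e-9,16,-6
EGEDEA-D,EGEDEA,11.35,4.34e-9,6,0.000,0.000,6.25e-9,7,-8
EGEDEA-E,EGEDEA,11.73,2.29e-9,6,0.000,0.000,3.55e-9,-5,-6
EGEDEA-F,EGEDEA,17.75,8.72e-14,6,0.000,0.000,1.19e-13,7,-4
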