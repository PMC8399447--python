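fragment,q_bt_e,amide_I_sum,amide_I_exp,acoo_sum,acoo_exp
EG,0.611,1656,1671,1644,1648
ED,0.850,1631,1632,1609,1608
EA,0.727,1651,1651,1642,1628
EGE,1.030,1617,,1641,
EDE,0.990,1634,,1609,
DEA,1.220,1635,,1618,
EGED,1.016,1676,1686,1620,1622
EDEA,1.444,1640,1641,1605,1602
EGEDE,1.240,1650,,1614,
GEDEA,1.530,1654,,1607,
EGEDEA,1.650,1658,1658,1610,1611
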