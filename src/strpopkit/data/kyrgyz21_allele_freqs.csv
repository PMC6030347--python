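alleles,D10S1248,D10S1435,D11S4463,D12ATA63,D14S1434,D17S1301,D18S853,D19S433,D1GATA113,D1S1677,D20S482,D22S1045,D2S1776,D2S441,D3S4529,D4S2408,D5S2500,D6S1017,D6S474,D9S1122,D1S1627
7,,,0.0033,,,0.0163,,,0.4267,,,,0.0033,,,,,,,,
8,,0.0016,0.0033,,,0.0016,0.0016,,0.0147,,,,0.0195,,,0.2590,,0.2362,,,
9,,0.0033,0.0016,,,0.0163,,,,,,,0.0798,,,0.3094,,0.0114,,,
9.1,,,,,,,,,,,,,,0.0033,,,,,,,
10,,,0.0179,,0.1629,0.0521,0.0098,,0.0033,,0.0440,0.0081,0.1107,0.2264,,0.2573,,0.3844,,0.0684,0.0505
11,0.0033,0.1156,0.0326,,0.1661,0.2980,0.3925,0.0033,0.1629,0.0016,0.0293,0.2606,0.2801,0.4577,,0.1466,,0.0375,,0.1743,0.0293
11.2,,,,,,,,,,0.0016,,,,,,,,,,,
11.3,,,,,,,,,,,,,,0.0212,,,,,,,
12,0.0537,0.3844,0.0505,0.3371,0.0179,0.3762,0.0700,0.0521,0.3534,0.0293,0.0700,0.0098,0.3681,0.0993,0.0163,0.0277,,0.2590,,0.2801,0.0130
12.2,0.0016,,,,,,,,,0.0065,,,,,,,,,,,
12.3,,,,,,,,,,,,,,0.0016,,,,,,,
13,0.2459,0.2655,0.2866,0.0798,0.3534,0.1873,0.2150,0.2296,0.0391,0.1678,0.2117,0.0130,0.1124,0.0195,0.2345,,0.0016,0.0700,0.0049,0.3844,0.4788
13.2,,0.0065,,,,,,0.0521,,,,,,,,,,,,,
14,0.2590,0.1889,0.2834,0.0244,0.2752,0.0505,0.2476,0.2785,,0.4463,0.4072,0.0358,0.0228,0.1384,0.2068,,0.2704,0.0016,0.3518,0.0651,0.4137
14.2,,,,,,,,0.0749,,,,,,,,,,,,,
15,0.2866,0.0065,0.2134,0.0554,0.0195,0.0016,0.0586,0.0977,,0.2720,0.1629,0.2606,0.0033,0.0326,0.3485,,,,0.3306,0.0130,0.0130
15.2,,,,,,,,0.1336,,,,,,,,,,,,,
16,0.1010,0.0033,0.1075,0.0847,0.0049,,0.0049,0.0261,,0.0749,0.0700,0.2427,,,0.1661,,,,0.1254,0.0147,0.0016
16.2,,,,,,,,0.0391,,,,,,,,,,,,,
17,0.0489,0.0244,,0.3681,,,,0.0081,,,0.0049,0.1401,,,0.0277,,0.3583,,0.1368,,
17.2,,,,,,,,0.0049,,,,,,,,,,,,,
18,,,,0.0489,,,,,,,,0.0261,,,,,0.2524,,0.0505,,
19,,,,,,,,,,,,0.0033,,,,,0.0098,,,,
20,,,,0.0016,,,,,,,,,,,,,0.0472,,,,
23,,,,,,,,,,,,,,,,,0.0423,,,,
24,,,,,,,,,,,,,,,,,0.0179,,,,
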