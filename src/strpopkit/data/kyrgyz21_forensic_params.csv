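locus,MP,PD,PIC,PE,TPI,HO,HE,hwe_p
D10S1248,0.087,0.913,0.7391,0.5656,2.291,0.7818,0.7745,0.8111
D10S1435,0.1204,0.8796,0.6888,0.4973,1.943,0.7427,0.7327,0.7153
D11S4463,0.0899,0.9101,0.7416,0.6259,2.693,0.8143,0.7766,0.1208
D12ATA63,0.1086,0.8914,0.6904,0.481,1.872,0.7329,0.7314,0.9861
D14S1434,0.1109,0.8891,0.702,0.514,2.0197,0.7524,0.7449,0.7861
D17S1301,0.1184,0.8816,0.6843,0.4389,1.7056,0.7068,0.7291,0.3621
D18S853,0.1196,0.8804,0.6867,0.4492,1.7443,0.7134,0.7293,0.4816
D19S433,0.0506,0.9494,0.809,0.7081,3.4886,0.8567,0.8284,0.2188
D1GATA113,0.1783,0.8217,0.6018,0.3896,1.535,0.6743,0.6647,0.7536
D1S1677,0.1373,0.8627,0.6434,0.3709,1.476,0.6612,0.6923,0.2227
D20S482,0.095,0.905,0.7181,0.4702,1.8274,0.7264,0.7502,0.3093
D22S1045,0.0842,0.9158,0.7495,0.6198,2.6466,0.8111,0.7828,0.2601
D2S1776,0.0966,0.9034,0.7181,0.4918,1.9188,0.7394,0.754,0.523
D2S441,0.1277,0.8723,0.6703,0.4338,1.6868,0.7036,0.7084,0.8188
D3S4529,0.0998,0.9002,0.711,0.4441,1.7247,0.7101,0.7515,0.0788
D4S2408,0.1113,0.8887,0.7041,0.5424,2.162,0.7687,0.749,0.447
D5S2500,0.1232,0.8768,0.6835,0.5028,1.9679,0.7459,0.731,0.5695
D6S1017,0.1237,0.8763,0.6757,0.4338,1.6868,0.7036,0.7234,0.4195
D6S474,0.129,0.871,0.6848,0.5309,2.1027,0.7622,0.7296,0.219
D9S1122,0.1131,0.8869,0.6924,0.4188,1.633,0.6938,0.7346,0.0993
D1S1627,0.2383,0.7617,0.5144,0.2565,1.1629,0.57,0.5955,0.3388
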