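subject_id,A_U_BV,A_V_BV,alpha_U,alpha_V,K_P_BV,G_U_T,G_V_T,G_V_L,P_U_T,P_V_L,K_P_H,K_I_H,G_BV,G_HR,A_SV,r_SV,K_P_SV,A_BP,K_P_BP,r_BP,HCT0,BV0,H0,SV0,TPR0
LR1,-0.0978,-0.0069,0.3108,0.2193,0.3807,0.2760,63.9160,38.9270,0.0021,0.8518,0.0021,0.0019,0.0040,0.0007,-0.0039,0.0559,0.0034,-0.0041,0.0055,72.0940,21.6000,2.3380,62.9790,0.0559,21.8780
LR2,-0.1450,-0.0072,-0.8142,0.3547,0.3846,0.1064,0.0003,0.9570,0.0195,0.3578,0.0000,0.0009,0.0061,0.0008,-0.0000,0.0589,0.0116,-0.2405,0.1888,75.2050,23.9400,2.5723,78.4800,0.0427,23.5830
LR3,-0.7551,-0.0028,-0.1490,0.5893,0.1375,0.0106,0.0487,0.0712,0.1226,0.5355,0.0323,0.0165,0.0147,0.1296,-0.0013,0.0534,0.0246,-0.0244,0.0117,71.5920,31.7000,1.8895,77.8610,0.0534,24.8240
LR4,-0.5425,-0.0051,-0.3322,0.4104,0.1352,5.0298,7.6321,0.5671,0.5778,0.0000,0.0615,0.0098,0.0044,0.0032,-0.0000,0.0863,0.0249,-0.2796,0.1252,53.0330,28.8300,2.4884,52.4690,0.0572,23.0260
LR5,-0.5013,-0.0255,-0.4886,0.3221,0.0688,0.4415,34.0430,28.7940,0.0064,0.7681,0.1290,0.0368,0.0031,0.0005,-0.0042,0.0407,0.0041,-0.0155,0.0174,62.1920,28.5000,2.7221,82.2410,0.0407,24.6720
LR6,-0.6107,-0.0104,-0.3297,0.2495,0.0861,8.5914,19.7470,3.2933,0.6000,0.1969,0.0045,0.0014,0.0163,0.0003,-0.0000,0.0368,0.0186,-0.4590,0.1840,58.1140,22.4960,1.9374,101.2200,0.0198,23.3810
LR7,-0.0681,-0.0108,0.1302,0.1461,0.3919,10.8640,0.0064,5.0610,0.5914,0.2400,0.0086,0.0009,0.0239,0.0001,-0.0029,0.0324,0.0003,-0.3342,0.2014,73.2170,30.3000,2.9268,101.8300,0.0324,23.2380
LR8,-0.3915,-0.0023,-0.6154,0.4163,0.0394,0.0000,5.8500,8.1290,0.0026,0.4058,0.0167,0.0023,0.0158,0.0003,-0.0097,0.0372,0.0097,-0.1602,0.3587,70.1100,23.8500,2.4996,86.0000,0.0372,25.6250
LR9,-0.3996,-0.0039,-0.3846,0.2086,0.0736,27.4100,13.0470,5.3117,0.5911,0.2006,0.0000,0.0018,0.0216,0.0000,-0.0000,0.0186,0.0100,-0.0000,0.0016,92.0680,20.4000,2.5730,96.4900,0.0442,24.0750
LR10,-0.7050,-0.0095,-0.3070,0.4492,0.1310,16.6650,30.2970,4.4546,0.4740,0.1837,0.0018,0.0021,0.0252,0.0001,-0.0000,0.0363,0.0000,-0.3716,0.2477,70.4470,26.1000,2.1358,80.0040,0.0362,35.8620
LR11,-0.4477,-0.0353,-0.4845,-0.1170,0.3171,2.1241,85.8680,65.7530,0.3140,0.8472,0.0159,0.0185,0.0257,0.0004,-0.0006,0.0638,0.0006,-0.6096,0.2021,68.2090,21.4200,2.2085,58.0000,0.0638,21.0810
LR12,-0.8273,-0.0072,-0.0678,0.3589,0.2275,1.7087,0.0126,19.4120,0.3326,0.5834,0.0007,0.0011,0.0200,0.0002,-0.0011,0.0233,0.0662,-0.0135,0.0262,64.9880,27.1475,1.7498,91.0840,0.0227,31.2000
LR13,-0.8332,-0.0045,-0.0975,0.3986,0.3767,8.9324,23.4210,143.150,0.4994,0.9933,0.0122,0.0001,0.0000,0.0010,-0.0000,0.0241,0.1194,-0.7064,0.5237,70.5550,22.0000,1.9840,70.3100,0.0420,25.5170
LR14,-0.7081,-0.0031,-0.2577,0.9681,0.1062,15.0990,5.8894,10.4790,0.4896,0.3374,0.0000,0.0011,0.0451,0.0001,-0.0004,0.0641,0.0006,-0.5601,0.1440,73.7630,24.1756,2.7041,78.0600,0.0641,19.7990
LR15,-0.8669,-0.0060,-0.0015,0.2671,1.0134,0.0860,0.3959,11.7090,0.0576,0.4536,0.1433,0.3791,0.0003,0.0008,-0.0103,0.0507,0.0139,-0.0136,0.0117,54.1830,22.8191,1.6075,71.0230,0.0507,25.7690
LR16,-0.1341,-0.0045,-0.1310,0.6688,0.1417,0.9799,0.0046,1.2366,0.0002,0.0003,0.0000,0.0009,0.0411,0.0003,-0.0025,0.0635,0.0025,-0.5815,0.2559,84.6170,32.7114,2.7728,74.0000,0.0635,19.5740
LR17,-0.3874,-0.0146,-0.4408,0.4043,0.2636,2.9159,158.710,49.3460,0.1444,0.6857,0.0166,0.0021,0.0000,0.0004,-0.0000,0.0618,0.0009,-0.4371,0.0390,75.2130,18.5103,2.5353,76.0000,0.0618,16.0690
LR18,-0.0108,-0.0045,0.6689,0.8124,0.2068,47.6860,0.0058,4.5771,0.5274,0.0016,0.0031,0.0009,0.0111,0.0001,-0.0062,0.0153,0.0050,-0.0002,0.0393,59.4830,23.2163,1.5727,144.6900,0.0153,35.6520
LR19,-0.0192,-0.0217,0.2444,0.5654,0.8488,1.4826,64.9970,18.3250,0.0252,0.3302,0.0000,0.0007,0.0122,0.0001,-0.0032,0.0235,0.0005,-0.0613,0.0933,56.3170,24.4936,3.0070,50.6580,0.0235,36.3290
LR20,-0.6975,-0.0014,-0.2900,1.4417,0.1304,5.6959,30.4410,4.1683,0.4622,0.2455,0.0127,0.0013,0.0000,0.0009,-0.0061,0.0486,0.0053,-0.0195,0.0000,90.0000,23.6109,2.6526,77.7370,0.0486,23.2270
LR21,-0.0505,-0.0034,0.1805,0.5397,0.6838,1.9980,0.2040,3.9582,0.0074,0.0496,0.0001,0.0006,0.0205,0.0002,-0.0018,0.0383,0.0022,-0.0419,0.0019,84.0000,20.0870,2.1077,102.9700,0.0383,20.0860
LR22,-0.0564,-0.0038,0.2521,1.2610,0.9384,0.0000,0.0000,5.8679,0.0007,0.3803,0.0015,0.0019,0.0258,0.0000,-0.0000,0.0317,0.0097,-0.0005,0.0000,77.0000,28.0000,2.4154,89.4410,0.0565,13.8100
HEX1,-0.4134,-0.0108,-0.5858,0.0574,0.3597,2.8817,7.6022,0.1251,0.5052,0.0000,0.0000,0.0055,0.0086,0.0007,-0.0000,0.0479,0.0047,-0.1053,0.4848,82.5260,28.0600,2.3571,81.4080,0.0420,26.1400
HEX2,-0.0132,-0.0033,-0.0023,0.5381,0.2181,0.0826,0.0021,4.5615,0.0671,0.4849,0.0098,0.0035,0.0763,0.0005,-0.0000,0.0648,0.0049,-0.0176,0.0061,66.3600,32.1180,2.1296,51.8390,0.0635,33.0970
HEX3,-0.0089,-0.0188,0.2797,0.3800,0.5514,0.9835,16.7130,1.9736,0.0020,0.0007,0.0001,0.0010,0.0541,0.0004,-0.0000,0.0650,0.0000,-0.0093,0.0022,47.5560,26.5600,2.5882,62.8720,0.0650,20.1010
HEX4,-0.0475,-0.0179,-0.0857,0.0903,0.3710,0.9998,39.0210,28.3840,0.2056,0.7179,0.0008,0.0008,0.0316,0.0002,-0.0002,0.0425,0.0002,-0.5576,0.2294,69.2390,25.0090,2.3429,80.8320,0.0425,24.5480
HEX5,-0.3730,-0.5721,-0.6143,-0.4416,0.0129,2.6714,93.6290,5.0596,0.1272,0.1252,0.0353,0.0081,0.0285,0.0002,-0.0000,0.0380,0.0000,-0.0325,0.0118,44.3770,20.6590,1.9817,84.4890,0.0380,25.6670
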