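group_id,c1,c2,c3,c4,c5,c6,c7,c8,c9,cv_percent
1,179,180,177,181,182,178,177,182,180,1.08
2,152,151,153,149,150,149,151,152,148,1.11
3,286,290,291,287,287,288,290,287,288,0.60
4,171,169,167,172,173,168,170,172,169,1.19
5,347,350,351,350,349,347,348,347,350,0.45
6,121,118,119,120,117,119,118,121,120,1.17
7,773,770,768,769,771,770,772,768,770,0.22
8,528,525,526,523,525,524,529,526,527,0.36
9,153,152,149,148,151,152,149,150,148,1.24
10,407,403,405,404,406,402,403,407,405,0.45
11,1094,1092,1095,1088,1089,1090,1092,1091,1093,0.21
12,163,167,165,164,163,164,166,165,164,0.81
13,903,905,899,902,907,900,902,905,901,0.29
14,309,312,310,307,308,306,311,312,310,0.69
15,455,456,451,456,457,453,452,451,454,0.50
16,789,783,786,784,782,785,783,780,781,0.35
17,471,470,469,470,468,472,466,471,467,0.43
18,216,214,216,213,215,214,212,216,215,0.66
19,614,613,615,610,616,612,613,611,616,0.35
20,107,109,111,112,109,111,108,110,112,1.61
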