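patient,vessel,proximal,stenotic,distal,ccia,ifr,ffr
1,LAD,1706,1041,1382,0.61,,0.89
2,RCA,782,601,824,0.77,1.03,0.94
3,LAD,448,491,801,1.10,0.99,0.90
4,LAD,1007,657,288,0.65,0.95,0.87
5,LAD,1257,452,745,0.36,0.67,0.77
6,LCx,856,225,922,0.26,0.81,0.59
7,LCx,660,113,505,0.17,0.72,0.63
8,LAD,1282,824,1003,0.64,,0.70
9,LAD,862,607,964,0.70,0.80,0.59
10,LAD,2371,1030,1258,0.43,0.92,0.72
11,RCA,354,162,287,0.46,0.72,0.57
12,LAD,519,220,431,0.42,0.85,0.79
13,LAD,212,91.89,104,0.43,,0.72
14,LCx,477,48,794,0.10,,0.74
15,LAD,416,379,470,0.91,1.03,0.87
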