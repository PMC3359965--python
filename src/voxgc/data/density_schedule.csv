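model_id,frac_xx,frac_yy,frac_yx,frac_xy
1,0.0656,0.0592,0.0493,0.0420
2,0.0656,0.0592,0.0473,0.0373
3,0.0656,0.0592,0.0453,0.0427
4,0.0656,0.0592,0.0400,0.0433
5,0.0656,0.0592,0.0427,0.0453
6,0.0656,0.0592,0.0413,0.0520
7,0.0656,0.0592,0.0320,0.0580
8,0.0656,0.0592,0.0340,0.0507
9,0.0978,0.0984,0.0973,0.0553
10,0.0978,0.0984,0.0860,0.0727
11,0.0978,0.0984,0.0827,0.0760
12,0.0978,0.0984,0.0860,0.0607
13,0.0978,0.0984,0.0907,0.0680
14,0.0978,0.0984,0.0713,0.0847
15,0.0978,0.0984,0.0787,0.0800
16,0.0978,0.0984,0.0713,0.0907
17,0.1300,0.1376,0.1233,0.0933
18,0.1300,0.1376,0.1220,0.1073
19,0.1300,0.1376,0.1187,0.1107
20,0.1300,0.1376,0.1300,0.0993
21,0.1300,0.1376,0.1193,0.1147
22,0.1300,0.1376,0.0993,0.1213
23,0.1300,0.1376,0.0980,0.1313
24,0.1300,0.1376,0.0880,0.1327
25,0.1944,0.1768,0.1800,0.0920
26,0.1944,0.1768,0.1727,0.0933
27,0.1944,0.1768,0.1587,0.1473
28,0.1944,0.1768,0.1560,0.1500
29,0.1944,0.1768,0.1593,0.1580
30,0.1944,0.1768,0.1413,0.1473
31,0.1944,0.1768,0.1373,0.1627
32,0.1944,0.1768,0.1240,0.1647
33,0.1944,0.1964,0.1853,0.1500
34,0.1944,0.1964,0.1707,0.1460
35,0.2267,0.2160,0.1807,0.1620
36,0.2267,0.2160,0.2000,0.1920
37,0.2267,0.2160,0.1800,0.1767
38,0.2267,0.2160,0.1727,0.2193
39,0.1944,0.1964,0.1367,0.1860
40,0.2267,0.2160,0.1687,0.2160
41,0.2589,0.2552,0.2380,0.2200
42,0.2267,0.2356,0.2113,0.1947
43,0.2267,0.2356,0.2213,0.1927
44,0.2267,0.2356,0.2113,0.2180
45,0.2589,0.2552,0.2220,0.2360
46,0.2267,0.2356,0.2027,0.2113
47,0.2267,0.2356,0.1740,0.2013
48,0.2589,0.2552,0.1720,0.2613
49,0.2911,0.2944,0.2847,0.2467
50,0.2589,0.2552,0.2387,0.1773
51,0.2911,0.2944,0.2540,0.2680
52,0.2589,0.2552,0.2373,0.2120
53,0.2589,0.2552,0.1880,0.2280
54,0.2911,0.2944,0.2367,0.2947
55,0.2911,0.2944,0.2053,0.2680
56,0.2911,0.2944,0.1827,0.2907
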