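splicing,pct_stem,pct_eloop,pct_gc_stem,pct_gc_loop
1,54.5,40.0,33.3,50.0
2,54.5,40.0,33.3,50.0
3,54.5,40.0,33.3,50.0
4,54.5,40.0,33.3,50.0
5,54.5,40.0,33.3,50.0
6,54.5,40.0,33.3,50.0
7,45.5,33.3,40.0,41.7
8,36.4,28.6,25.0,50.0
9,36.4,28.6,37.5,42.9
10,36.4,28.6,37.5,42.9
11,45.5,50.0,20.0,58.3
12,54.5,60.0,33.3,50.0
13,63.6,75.0,42.9,37.5
14,72.7,100.0,43.8,33.3
15,63.6,75.0,42.9,37.5
16,54.5,60.0,33.3,50.0
17,45.5,50.0,20.0,58.3
18,36.4,42.9,25.0,50.0
19,45.5,83.3,30.0,50.0
20,45.5,83.3,30.0,13.3
21,45.5,33.3,40.0,41.7
22,54.5,40.0,33.3,50.0
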