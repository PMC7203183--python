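subelement,ecoli_pct_stem,ecoli_pct_eloop,ecoli_pct_gc_stem,ecoli_pct_gc_loop,streptomyces_pct_stem,streptomyces_pct_eloop,streptomyces_pct_gc_stem,streptomyces_pct_gc_loop
h1,63.6,62.5,42.9,25.0,48.9,33.3,52.2,41.7
h2,72.7,50.0,43.8,33.3,60.0,0.0,66.7,0.0
h3,54.5,50.0,50.0,30.0,69.0,0.0,60.0,44.4
h4,45.5,25.0,30.0,42.9,88.9,0.0,87.5,50.0
h5,72.7,50.0,43.8,16.7,66.7,0.0,66.7,16.7
h6,63.6,37.5,35.7,37.5,61.1,28.6,59.1,50.0
h6a,54.5,30.0,41.7,30.0,0.0,0.0,,66.7
h7,63.6,62.5,42.9,37.5,69.6,0.0,71.9,28.6
h8,45.5,41.7,30.0,50.0,62.5,33.3,65.0,58.3
h9,72.7,50.0,31.3,66.7,62.9,30.8,68.2,30.8
h10,72.7,50.0,56.3,0.0,44.4,80.0,100.0,80.0
h11,54.5,50.0,58.3,20.0,60.0,35.0,60.0,45.0
h12,45.5,41.7,40.0,41.7,59.3,63.6,93.8,36.4
h13,63.6,37.5,50.0,25.0,43.5,92.3,80.0,53.8
h14,63.6,37.5,50.0,25.0,57.1,66.7,50.0,50.0
h15,72.7,50.0,37.5,50.0,52.9,25.0,66.7,37.5
h16,45.5,41.7,30.0,50.0,51.6,26.7,75.0,46.7
h17,81.8,75.0,38.9,25.0,43.9,52.2,72.2,34.8
h18,81.8,75.0,38.9,25.0,51.1,69.6,70.8,60.9
h19,45.5,25.0,20.0,50.0,0.0,0.0,,40.0
h20,63.6,37.5,50.0,12.5,55.2,0.0,81.3,38.5
h21,72.7,50.0,43.8,16.7,70.8,26.3,52.2,31.6
h22,36.4,21.4,50.0,28.6,80.0,0.0,44.4,66.7
h23,45.5,25.0,50.0,25.0,53.3,28.6,62.5,38.1
h23a,54.5,40.0,33.3,50.0,37.5,40.0,100.0,60.0
h24,54.5,50.0,58.3,20.0,52.2,40.9,79.2,31.8
h25,63.6,37.5,50.0,25.0,66.7,0.0,71.4,42.9
h26a,63.6,62.5,42.9,37.5,26.7,36.4,100.0,27.3
h26,54.5,30.0,25.0,60.0,76.2,93.3,58.3,26.7
h27,63.6,30.0,35.7,37.5,57.1,33.3,68.8,33.3
h28,54.5,30.0,41.7,30.0,85.7,0.0,75.0,50.0
h29,63.6,37.5,50.0,12.5,80.0,0.0,75.0,66.7
h30,63.6,62.5,42.9,37.5,71.4,0.0,65.0,50.0
h31,54.5,50.0,41.7,40.0,28.6,40.0,50.0,35.0
h32,72.7,50.0,31.3,66.7,82.4,0.0,64.3,0.0
h33,72.7,50.0,56.3,0.0,69.6,0.0,56.3,42.9
h33a,63.6,62.5,50.0,25.0,53.3,64.3,68.8,42.9
h34,54.5,50.0,50.0,30.0,75.6,0.0,67.6,27.3
h35,72.7,50.0,43.8,33.3,75.0,0.0,66.7,50.0
h36,72.7,50.0,56.3,0.0,54.5,80.0,50.0,60.0
h37,72.7,50.0,37.5,50.0,50.0,75.0,87.5,25.0
h38,27.3,18.8,83.3,25.0,80.0,0.0,70.8,33.3
h39,72.7,50.0,43.8,16.7,61.5,50.0,68.8,60.0
h40,81.8,75.0,38.9,25.0,42.9,25.0,75.0,56.3
h41,45.5,25.0,20.0,50.0,63.6,0.0,85.7,50.0
h41a,54.5,30.0,58.3,10.0,50.0,25.0,75.0,43.8
h42,81.8,75.0,38.9,25.0,39.0,32.0,75.0,44.0
h43,45.5,25.0,40.0,41.7,37.8,34.8,64.3,43.5
h44,27.3,18.8,66.7,25.0,59.8,11.6,79.7,39.5
h45,54.5,40.0,33.3,50.0,50.0,20.0,70.0,45.0
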