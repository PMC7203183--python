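subelement,homo_pct_stem,homo_pct_eloop,homo_pct_gc_stem,homo_pct_gc_loop,saccharomyces_pct_stem,saccharomyces_pct_eloop,saccharomyces_pct_gc_stem,saccharomyces_pct_gc_loop
h1,52.6,66.7,70.0,44.4,50.0,70.0,70.0,30.0
h2,36.4,57.1,50.0,0.0,50.0,0.0,50.0,0.0
h3,66.7,0.0,25.0,60.0,84.6,0.0,27.3,25.0
h4,30.8,0.0,50.0,44.4,25.0,0.0,0.0,33.3
h5,57.1,0.0,66.7,22.2,54.5,0.0,83.3,10.0
h6,35.0,38.5,50.0,50.0,35.9,40.0,57.1,20.0
h6a,50.0,0.0,133.3,33.3,75.0,0.0,66.7,50.0
h7,50.0,0.0,45.0,45.0,35.7,0.0,30.0,25.0
h8,31.4,14.3,56.3,45.7,41.9,20.0,50.0,20.0
h9,53.8,13.3,84.3,58.3,54.1,20.5,34.8,25.6
h10,66.7,66.7,88.9,77.8,66.7,62.5,75.0,37.5
h11,50.0,34.6,53.8,57.7,54.9,30.4,57.1,39.1
h12,53.3,57.1,125.0,57.1,72.0,57.1,55.6,42.9
h13,43.5,76.9,80.0,46.2,38.5,62.5,80.0,37.5
h14,42.9,50.0,66.7,37.5,42.9,50.0,66.7,50.0
h15,54.8,35.7,70.6,64.3,50.0,31.3,56.3,43.8
h16,64.9,30.8,50.0,23.1,61.1,28.6,59.1,21.4
h17,35.3,50.0,33.3,36.4,27.8,42.3,50.0,26.9
h18,47.1,25.9,62.5,48.1,49.0,16.0,62.5,52.0
h19,0.0,0.0,,12.5,0.0,0.0,,7.1
h20,72.7,0.0,37.5,50.0,60.9,0.0,35.7,44.4
h21,61.7,29.3,69.7,52.4,49.3,30.4,58.0,28.7
h22,59.5,0.0,68.2,33.3,57.1,0.0,70.8,38.9
h23,55.8,31.6,70.8,42.1,57.8,31.6,30.8,26.3
h23a,25.0,33.3,100.0,41.7,25.0,33.3,100.0,25.0
h24,45.3,31.0,66.7,31.0,46.2,32.1,50.0,32.1
h25,60.0,0.0,75.0,37.5,63.6,0.0,64.3,25.0
h26a,40.0,44.4,66.7,33.3,34.0,54.8,81.3,25.8
h26,76.9,44.4,70.0,77.8,40.0,44.4,33.3,22.2
h27,48.5,23.5,50.0,35.3,62.9,30.8,63.6,46.2
h28,80.0,0.0,53.6,100.0,75.7,0.0,53.6,100.0
h29,62.5,0.0,50.0,83.3,85.7,0.0,41.7,50.0
h30,69.2,0.0,83.3,75.0,71.4,0.0,75.0,75.0
h31,33.3,40.0,50.0,30.0,33.3,40.0,50.0,40.0
h32,66.7,0.0,100.0,33.3,85.7,0.0,75.0,0.0
h33,40.0,33.3,60.0,33.3,40.0,33.3,50.0,0.0
h33a,,,,,,,,
h34,63.8,0.0,60.0,105.9,66.7,0.0,56.3,56.3
h35,66.7,0.0,40.0,80.0,66.7,0.0,60.0,120.0
h36,60.0,100.0,33.3,75.0,60.0,100.0,33.3,50.0
h37,38.5,75.0,140.0,0.0,40.0,50.0,62.5,8.3
h38,66.7,0.0,62.5,50.0,84.2,0.0,81.3,0.0
h39,63.2,19.0,50.0,76.2,71.4,33.3,53.3,8.3
h40,55.2,38.5,75.0,23.1,69.0,33.3,55.0,33.3
h41,37.5,0.0,61.1,70.0,56.4,0.0,54.5,58.8
h41a,82.4,66.7,46.4,66.7,51.4,23.5,72.2,17.6
h42,37.8,43.5,78.6,30.4,42.1,45.5,56.3,27.3
h43,72.7,55.6,50.0,33.3,55.2,53.8,56.3,38.5
h44,61.9,9.4,69.8,45.3,63.8,7.8,55.6,37.3
h45,62.5,33.3,60.0,25.0,62.5,33.3,60.0,25.0
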