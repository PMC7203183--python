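subelement,phyl_rank,stru_rank,thermus_pct_stem,thermus_pct_eloop,thermus_pct_gc_stem,thermus_pct_gc_loop,sulfolobus_pct_stem,sulfolobus_pct_eloop,sulfolobus_pct_gc_stem,sulfolobus_pct_gc_loop
h1,25.0,3.3,43.5,30.8,60.0,30.8,19.0,0.0,50.0,58.8
h2,29.0,4.0,75.0,0.0,133.3,0.0,66.7,0.0,50.0,0.0
h3,10.0,4.0,62.5,0.0,60.0,50.0,71.4,0.0,75.0,25.0
h4,,7.0,94.1,0.0,93.8,0.0,100.0,,88.9,
h5,20.0,9.0,54.5,0.0,58.3,40.0,54.5,0.0,83.3,40.0
h6,10.0,12.0,72.7,25.0,81.3,58.3,62.1,54.5,61.1,45.5
h6a,,12.0,100.0,,66.7,,0.0,0.0,,87.5
h7,,15.0,81.0,0.0,79.4,25.0,68.1,0.0,81.3,20.0
h8,30.0,18.0,58.8,28.6,95.0,35.7,74.3,44.4,80.8,11.1
h9,21.0,18.0,55.2,30.8,81.3,38.5,72.2,60.0,57.7,30.0
h10,37.0,15.0,66.7,75.0,100.0,25.0,69.0,88.9,55.0,44.4
h11,2.0,19.0,63.6,37.5,53.6,56.3,58.3,35.0,78.6,35.0
h12,17.0,12.0,72.7,66.7,75.0,66.7,71.0,44.4,77.3,33.3
h13,24.0,17.0,43.5,92.3,100.0,53.8,58.3,60.0,71.4,50.0
h14,28.0,17.0,53.3,57.1,75.0,57.1,61.5,80.0,100.0,60.0
h15,16.0,7.0,52.9,25.0,77.8,31.3,58.8,28.6,90.0,28.6
h16,22.0,26.0,48.5,23.5,81.3,29.4,66.7,66.7,83.3,50.0
h17,12.0,26.0,36.0,12.5,100.0,37.5,64.5,63.6,70.0,9.1
h18,33.0,7.0,51.1,17.4,91.7,56.5,54.2,63.6,69.2,72.7
h19,22.0,4.0,0.0,0.0,,23.1,0.0,0.0,,33.3
h20,18.0,7.0,63.6,0.0,92.9,50.0,76.9,0.0,75.0,50.0
h21,27.0,20.0,56.5,25.0,134.6,40.0,73.8,29.4,81.3,23.5
h22,11.0,20.0,60.0,0.0,140.0,70.0,66.7,0.0,100.0,58.3
h23,7.0,20.0,48.9,26.1,72.7,34.8,62.2,35.3,67.9,35.3
h23a,38.0,24.0,14.3,33.3,100.0,58.3,20.0,100.0,100.0,68.8
h24,8.0,5.0,51.1,39.1,87.5,30.4,54.2,40.9,88.5,27.3
h25,23.0,3.0,72.0,0.0,100.0,42.9,77.8,0.0,85.7,50.0
h26a,39.0,21.0,25.0,33.3,100.0,25.0,26.7,36.4,100.0,45.5
h26,9.0,21.0,80.0,60.0,70.0,20.0,88.2,75.0,63.3,0.0
h27,19.0,3.0,45.2,23.5,85.7,35.3,69.2,50.0,55.6,37.5
h28,9.0,3.0,73.7,0.0,71.4,50.0,83.3,0.0,70.0,25.0
h29,36.0,6.0,83.3,0.0,70.0,0.0,85.7,0.0,58.3,50.0
h30,15.0,8.0,78.6,0.0,59.1,66.7,74.1,0.0,75.0,57.1
h31,34.0,10.0,28.6,40.0,50.0,35.0,14.3,33.3,100.0,33.3
h32,19.0,10.0,77.8,0.0,85.7,25.0,82.4,0.0,92.9,33.3
h33,20.0,11.0,66.7,0.0,62.5,37.5,55.3,33.3,76.9,38.1
h33a,,27.0,68.6,72.7,87.5,36.4,,,,
h34,3.0,11.0,63.6,0.0,82.1,37.5,73.2,0.0,80.0,72.7
h35,35.0,22.0,80.0,0.0,66.7,66.7,83.3,0.0,60.0,133.3
h36,26.0,22.0,42.9,100.0,166.7,50.0,42.9,100.0,33.3,50.0
h37,31.0,23.0,44.4,60.0,87.5,20.0,44.4,60.0,100.0,30.0
h38,,22.0,69.0,0.0,40.0,44.4,89.5,0.0,70.6,50.0
h39,32.0,22.0,55.6,62.5,100.0,62.5,77.8,100.0,57.1,100.0
h40,21.0,25.0,51.9,30.8,92.9,30.8,56.0,36.4,92.9,45.5
h41,,14.0,51.9,0.0,78.6,23.1,55.2,0.0,93.8,30.8
h41a,14.0,14.0,45.7,36.8,100.0,31.6,75.0,50.0,66.7,25.0
h42,17.0,16.0,40.0,33.3,75.0,54.2,48.8,38.1,75.0,52.4
h43,18.0,6.0,40.0,47.6,78.6,33.3,47.4,25.0,77.8,45.0
h44,1.0,1.0,58.3,9.3,93.3,48.8,55.8,10.9,69.0,54.3
h45,13.0,2.0,54.1,23.5,65.0,47.1,58.8,28.6,5.0,50.0
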