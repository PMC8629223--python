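# Side-view cow silhouette polygon, one vertex per row, in body coordinates
# u (0=head end, 1=tail end), v (0=top, 1=ground). Closed implicitly.
u,v
0.055,0.400
0.100,0.345
0.160,0.330
0.220,0.300
0.400,0.265
0.600,0.260
0.760,0.285
0.825,0.320
0.840,0.450
0.815,0.575
0.825,0.880
0.765,0.880
0.750,0.600
0.620,0.615
0.460,0.625
0.345,0.615
0.335,0.880
0.275,0.880
0.265,0.585
0.230,0.545
0.175,0.500
0.105,0.460
0.045,0.455
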