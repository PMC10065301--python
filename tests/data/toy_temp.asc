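ncols 6
nrows 6
xllcorner 100
yllcorner 20
cellsize 0.5
NODATA_value -9999
-9999 1 2 3 4 5
0 1 2 3 4 5
0 1 2 3 4 5
0 1 2 3 4 5
0 1 2 3 4 5
0 1 2 3 4 -9999
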