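ncols 6
nrows 6
xllcorner 100
yllcorner 20
cellsize 0.5
NODATA_value -9999
-9999 5 5 5 5 5
4 4 4 4 4 4
3 3 3 3 3 3
2 2 2 2 2 2
1 1 1 1 1 1
0 0 0 0 0 -9999
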