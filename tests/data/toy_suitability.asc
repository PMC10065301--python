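ncols 6
nrows 6
xllcorner 100
yllcorner 20
cellsize 0.5
NODATA_value -9999
-9999 0.6 0.7 0.8 0.9 1
0.4 0.5 0.6 0.7 0.8 0.9
0.3 0.4 0.5 0.6 0.7 0.8
0.2 0.3 0.4 0.5 0.6 0.7
0.1 0.2 0.3 0.4 0.5 0.6
0 0.1 0.2 0.3 0.4 -9999
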