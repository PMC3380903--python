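year,dekad_index,rain_mm
1,1,34.9
1,2,22.4
1,3,0.6
1,4,33.8
1,5,0.0
1,6,57.6
1,7,73.4
1,8,161.8
1,9,112.9
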