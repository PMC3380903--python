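year,dekad_index,rain_mm
1,1,5.8
1,2,3.6
1,3,0.0
1,4,9.5
1,5,4.1
1,6,23.5
1,7,12.6
1,8,2.0
1,9,96.1
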