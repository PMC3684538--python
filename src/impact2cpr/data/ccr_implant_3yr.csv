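year_offset,ccr
0,1.0
1,0.87
2,0.74
3,0.60
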