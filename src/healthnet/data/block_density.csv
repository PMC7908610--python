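block,density_1,density_2,density_3,density_4,image_1,image_2,image_3,image_4
1,0.667,0.133,0.278,0.061,1,0,1,0
2,0.067,0.400,0.133,0.345,0,1,0,1
3,0.778,0.517,0.038,0.068,1,1,0,0
4,0.697,0.909,0.061,0.009,1,1,0,0
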