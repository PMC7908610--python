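block,n_members,receive_inside,receive_outside,send_inside,send_outside,expected_ratio,actual_ratio,role
1,3,4,52,4,14,6.667,22.222,net_beneficial
2,5,8,83,8,28,13.333,22.222,bidirectional_spillover
3,12,5,26,5,68,36.667,6.849,broker
4,11,1,30,1,81,33.333,1.219,net_spillover
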