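province,out_degree,in_degree,degree_centrality,benefit,degree_rank,closeness_centrality,closeness_rank,betweenness_centrality,betweenness_rank
Shanghai,9,27,93.333,Yes,1,93.750,1,15.051,1
Jiangsu,4,28,93.333,Yes,1,93.750,1,15.051,1
Beijing,5,23,76.667,Yes,2,81.081,2,10.972,2
Tianjin,5,22,76.667,Yes,2,81.081,2,10.811,3
Zhejiang,5,19,66.667,Yes,3,75.000,3,6.608,4
Guangdong,11,10,46.667,No,4,65.217,4,2.286,5
Shandong,8,11,43.333,Yes,5,63.830,5,1.605,6
Gansu,11,3,36.667,No,6,61.224,6,0.980,8
Fujian,7,7,36.667,Balance,6,61.224,6,1.204,7
Henan,6,9,30.000,Yes,7,58.824,7,0.508,9
Guangxi,7,4,30.000,No,7,58.824,7,0.393,12
Chongqing,8,4,30.000,No,7,58.825,7,0.362,13
Yunnan,8,2,26.667,No,8,57.962,8,0.347,14
Tibet,8,0,26.667,No,8,57.692,9,0.335,15
Sichuan,8,2,26.667,No,8,57.692,9,0.294,16
Hainan,8,1,26.667,No,8,57.692,9,0.235,18
Guizhou,8,2,26.667,No,8,57.692,9,0.347,14
Anhui,3,8,26.667,Yes,8,57.692,9,0.403,11
Xinjiang,7,0,23.333,No,9,56.604,10,0.190,19
Shaanxi,7,1,23.333,No,9,56.604,10,0.106,21
Jiangxi,7,6,23.333,No,9,56.604,10,0.256,17
Hunan,7,3,23.333,No,9,56.604,10,0.235,18
Hubei,7,3,23.333,No,9,56.604,10,0.461,10
Heilongjiang,7,1,23.333,No,9,56.604,10,0.149,20
Qinghai,6,1,20.000,No,10,55.556,11,0.077,23
Jilin,6,1,20.000,No,10,55.556,11,0.077,23
Inner Mongolia,6,1,20.000,No,10,55.556,11,0.089,22
Shanxi,5,4,20.000,No,10,55.556,11,0.089,22
Hebei,5,5,20.000,Balance,10,55.556,11,0.089,22
Liaoning,5,0,16.667,No,11,54.545,12,0.077,23
Ningxia,5,1,16.667,No,11,54.545,12,0.050,24
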