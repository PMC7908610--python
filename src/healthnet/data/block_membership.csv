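province,block
Beijing,1
Tianjin,1
Shandong,1
Jiangsu,2
Guangdong,2
Fujian,2
Zhejiang,2
Shanghai,2
Jilin,3
Hebei,3
Inner Mongolia,3
Shaanxi,3
Liaoning,3
Qinghai,3
Heilongjiang,3
Henan,3
Hubei,3
Shanxi,3
Ningxia,3
Chongqing,3
Hunan,4
Hainan,4
Guangxi,4
Guizhou,4
Yunnan,4
Tibet,4
Anhui,4
Gansu,4
Jiangxi,4
Sichuan,4
Xinjiang,4
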