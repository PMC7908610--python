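province,population_10k,bed_utilization_pct,consultation_burden_per_day
Guangdong,11169,84.0,10.6
Shandong,10006,83.4,5.9
Henan,9559,88.4,6.1
Sichuan,8302,91.3,7.0
Jiangsu,8029,87.5,8.7
Hebei,7520,83.7,5.2
Hunan,6860,85.2,4.6
Anhui,6255,86.2,6.2
Hubei,5902,92.7,6.9
Zhejiang,5657,89.4,11.4
Guangxi,4885,87.7,7.8
Yunnan,4801,83.2,7.6
Jiangxi,4622,85.8,5.9
Liaoning,4369,82.0,5.3
Fujian,3911,83.1,8.6
Shaanxi,3835,83.7,6.0
Heilongjiang,3789,78.9,4.7
Shanxi,3702,77.6,4.2
Guizhou,3580,79.9,5.7
Chongqing,3075,84.1,7.2
Jilin,2717,77.6,5.0
Gansu,2626,81.6,6.2
Inner Mongolia,2529,74.7,5.1
Xinjiang,2445,85.0,5.8
Shanghai,2418,95.4,14.8
Beijing,2171,82.4,9.3
Tianjin,1557,78.1,10.4
Hainan,926,81.1,6.4
Ningxia,682,80.8,6.8
Qinghai,598,70.6,5.3
Tibet,337,72.1,5.9
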