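province,basin
Hunan,Yangtze River Basin
Hubei,Yangtze River Basin
Jiangxi,Yangtze River Basin
Anhui,Yangtze River Basin
Jiangsu,Yangtze River Basin
Shanghai,Yangtze River Basin
Tibet,Southwest Basin
Sichuan,Southwest Basin
Chongqing,Southwest Basin
Guizhou,Southwest Basin
Yunnan,Southwest Basin
Guangdong,Pearl River Basin
Guangxi,Pearl River Basin
Hainan,Pearl River Basin
Fujian,Southeast Basin
Zhejiang,Southeast Basin
Beijing,Yellow River Basin and Huaihe River Basin
Tianjin,Yellow River Basin and Huaihe River Basin
Hebei,Yellow River Basin and Huaihe River Basin
Shanxi,Yellow River Basin and Huaihe River Basin
Shandong,Yellow River Basin and Huaihe River Basin
Henan,Yellow River Basin and Huaihe River Basin
Shaanxi,Yellow River Basin and Huaihe River Basin
Qinghai,Yellow River Basin and Huaihe River Basin
Heilongjiang,Songhua and Liaohe River Basin
Jilin,Songhua and Liaohe River Basin
Liaoning,Songhua and Liaohe River Basin
Xinjiang,Continental Basin
Ningxia,Continental Basin
Gansu,Continental Basin
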