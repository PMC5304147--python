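code,name,origin,wis,note
ND12,NanDou No. 12,"Nanchong, Sichuan",0.51,cultivar
14011,LUOSHI,"Xichang, Sichuan",0.52,wild
14022,Gongxuan No. 5,"Zigong, Sichuan",0.97,cultivar
14015,HUI,"Xichang, Sichuan",1.02,wild
14027,MAO,"Jiuzaigou, Sichuan",1.06,wild
14057,BAYUE,"Pingchang, Sichuan",1.09,wild
C103,Nan032-4,"Nanchong, Sichuan",1.26,cultivar
14059,DONG,"Yibing, Sichuan",1.80,wild
14055,YINGSHAN,"Muchuan, Sichuan",1.82,wild
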