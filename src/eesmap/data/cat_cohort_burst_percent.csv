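animal,channel,rostral_pct,caudal_pct
101,CYST,3077,80
103,CYST,4600,3400
104,CYST,9500,1100
105,CYST,14500,5700
106,CYST,2070,81
101,Detr,1630,170
103,Detr,360,180
104,Detr,2050,450
105,Detr,2500,120
106,Detr,360,85
101,EUS,300,555
103,EUS,820,850
104,EUS,115,270
105,EUS,230,900
106,EUS,110,1010
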