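mountain,location,elevation,n_all,nights_all,pct_all,n_ground,nights_ground,pct_ground
Kinabalu,500,500,33,300,11.0,30,285,10.5
Kinabalu,900,900,20,360,5.6,20,360,5.6
Kinabalu,1500,1500,36,360,10.0,36,360,10.0
Kinabalu,2200,2200,35,434,8.1,34,427,8.0
Kinabalu,2700,2700,60,390,15.4,60,390,15.4
Kinabalu,3200,3200,29,200,14.5,29,200,14.5
Tambuyukon,500,500,78,1713,4.6,75,1588,4.7
Tambuyukon,900,900,24,992,2.4,24,956,2.5
Tambuyukon,1300,1300,53,712,7.4,52,702,7.4
Tambuyukon,1600,1600,22,1036,2.1,22,1025,2.1
Tambuyukon,2000,2000,55,1036,5.3,55,988,5.6
Tambuyukon,2400,2400,67,698,9.6,67,698,9.6
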