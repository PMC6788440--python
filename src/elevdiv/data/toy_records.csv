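record_id,species,mountain,location,elevation,trap_class,recapture,capture_day
t001,Rattus toyensis,North,500,480,ground,False,1
t002,Rattus toyensis,North,500,510,ground,False,2
t003,Tupaia toyana,North,500,505,ground,False,2
t004,Tupaia toyana,North,1500,1490,ground,False,1
t005,Maxomys toyi,North,1500,1515,ground,False,3
t006,Tupaia toyana,North,1500,1500,ground,True,4
t007,Lenothrix toyi,North,500,495,arboreal,False,3
t008,Suncus sp.,North,500,500,pitfall,False,4
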