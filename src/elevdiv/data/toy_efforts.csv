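mountain,location,trap_class,trap_nights
North,500,ground,120
North,500,arboreal,20
North,500,pitfall,15
North,1500,ground,100
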