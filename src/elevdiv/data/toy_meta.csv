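species,endemic
Rattus toyensis,non_endemic
Tupaia toyana,endemic
Maxomys toyi,endemic
Lenothrix toyi,non_endemic
Suncus sp.,unknown
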