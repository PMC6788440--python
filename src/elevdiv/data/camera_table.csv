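camera_id,elevation,common_name,species,n_series,camera_nights,printed_rate,denominator_ambiguous
1,500,Pig-tailed Macaque,Macaca nemestrina,1,42,2.38,False
1,500,Common Porcupine,Hystrix brachyura,2,42,4.76,False
1,500,Mouse Deer,Tragulus sp.,2,42,4.76,False
1,500,Muntjac,Muntiacus sp.,1,42,2.38,False
1,500,Sambar Deer,Rusa unicolor,1,42,2.38,False
2,900,Malay Civet,Viverra tangalunga,2,42,9.52,True
2,900,Banded Linsang,Prionodon linsang,1,42,2.38,False
4,1300,Malay Civet,Viverra tangalunga,1,29,3.45,False
4,1300,Masked Palm Civet,Paguma larvata,1,29,3.45,False
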