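pdb_id,target,compound,energy
5T01,JUN,Quercetin,-8.8
3ZU7,MAPK1,Quercetin,-8.8
5T01,JUN,Kaempferol,-8.7
2UVM,AKT1,Quercetin,-8.4
2UVM,AKT1,Kaempferol,-8.1
4QAF,VEGFA,Diosgenin,-8.1
4H82,MMP9,Quercetin,-8.1
2TNF,TNF,Quercetin,-8.1
2NO3,MAPK8,Kaempferol,-8.0
4QAF,VEGFA,Quercetin,-7.9
2TNF,TNF,Kaempferol,-7.9
2UVM,AKT1,Diosgenin,-7.7
5T01,JUN,Beta-sitosterol,-7.7
2RUK,TP53,Diosgenin,-7.6
2RUK,TP53,Quercetin,-6.9
2KV4,EGF,Quercetin,-6.9
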