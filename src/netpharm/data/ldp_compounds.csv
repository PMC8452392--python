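mol_id,name,herbs,ob_percent,dl
MOL000273,"(2R)-2-[(3S,5R,10S,13R,14R,16R,17R)-3,16-Dihydroxy-4,4,10,13,14-pentamethyl-2,3,5,6,12,15,16,17-octahydro-1H-cyclopenta[a]phenanthren-17-yl]-6-methylhept-5-enoic acid",Fuling,30.93,0.81
MOL000275,Trametenolic acid,Fuling,38.71,0.8
MOL000283,Ergosterol peroxide,Fuling,40.36,0.81
MOL000279,Cerevisterol,Fuling,37.96,0.77
MOL000296,Hederagenin,Fuling,36.91,0.75
MOL000282,"Ergosta-7,22E-dien-3beta-ol",Fuling,43.51,0.72
MOL000098,Quercetin,Mudanpi,46.43,0.28
MOL000211,Mairin,Mudanpi,55.38,0.78
MOL000422,Kaempferol,Mudanpi,41.88,0.24
MOL000492,(+)-Catechin,Mudanpi,54.83,0.24
MOL007374,5-[[5-(4-Methoxyphenyl)-2-furyl]methylene]barbituric- acid,Mudanpi,43.44,0.3
MOL000322,Kadsurenone,Shanyao,54.72,0.38
MOL000546,Diosgenin,Shanyao,80.88,0.81
MOL000953,CLR,Shanyao,37.87,0.68
MOL001559,Piperlonguminine,Shanyao,30.71,0.18
MOL001736,(-)-Taxifolin,Shanyao,60.51,0.27
MOL005430,Hancinone C,Shanyao,59.05,0.39
MOL005435,24-Methylcholest-5-enyl-3belta-O-glucopyranoside_qt,Shanyao,37.58,0.72
MOL005438,Campesterol,Shanyao,37.58,0.71
MOL005440,Isofucosterol,Shanyao,43.78,0.76
MOL005458,Dioscoreside C_qt,Shanyao,36.38,0.87
MOL005465,AIDS180907,Shanyao,45.33,0.77
MOL000449,Stigmasterol,"Shanyao, Shanzhuyu, Shudihuang",43.83,0.76
MOL005531,Telocinobufagin,Shanzhuyu,69.99,0.79
MOL000358,Beta-sitosterol,Shanzhuyu,36.91,0.75
MOL005481,"2,6,10,14,18-Pentamethylicosa-2,6,10,14,18-pentaene",Shanzhuyu,33.4,0.24
MOL001495,Ethyl linolenate,Shanzhuyu,46.1,0.2
MOL005503,Cornudentanone,Shanzhuyu,39.66,0.33
MOL002879,Diop,Shanzhuyu,43.59,0.39
MOL002883,Ethyl oleate (NF),Shanzhuyu,32.4,0.19
MOL001771,Poriferast-5-en-3beta-ol,Shanzhuyu,36.91,0.75
MOL005530,Hydroxygenkwanin,Shanzhuyu,36.47,0.27
MOL001494,Mandenol,Shanzhuyu,42,0.19
MOL008457,Tetrahydroalstonine,Shanzhuyu,32.42,0.81
MOL000831,Alisol B monoacetate,Zexie,35.58,0.81
MOL000849,16beta-Methoxyalisol B monoacetate,Zexie,32.43,0.77
MOL000853,Alisol B,Zexie,36.76,0.82
MOL000856,Alisol C monoacetate,Zexie,33.06,0.83
MOL000862,"[(1S,3R)-1-[(2R)-3,3-Dimethyloxiran-2-yl]-3-[(5R,8S,9S,10S,11S,14R)-11-hydroxy-4,4,8,10,14-pentamethyl-3-oxo-1,2,5,6,7,9,11,12,15,16-decahydrocyclopenta[a]phenanthren-17-yl]butyl] acetate",Zexie,35.58,0.81
MOL002464,1-Monolinolein,Zexie,37.18,0.3
MOL000359,Sitosterol,"Zexie, Mudanpi, Shanzhuyu, Shudihuang",36.91,0.75
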