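taxon,cluster,accession,bsgol,branch_length,gol_rate,normalized_gol_rate,nprs_rate,n_trna,n_intronic_orfs,n_introns,n_repeats,n_intergenic_repeats,genome_size
Cryptococcus neoformans,basidiomycetes,NC_004336,3.50E-01,0.7,1.05E+00,2.96E+00,0.002,20,1,2,128,9,24874
Moniliophthora perniciosa,basidiomycetes,NC_005927,1.16E-01,0.22,3.36E-01,7.89E-01,0.001,30,11,13,1648,272,109103
Microbotryum violaceum-Sl,basidiomycetes,NC_020353,3.12E-01,0.25,5.62E-01,1.32E+00,0.0007,20,33,22,1003,380,107808
Phakopsora pachyrhizi,basidiomycetes,NC_014344,2.38E-01,0.7,9.38E-01,2.11E+00,0.002,24,2,5,1898,31,31825
Pleurotus ostreatus,basidiomycetes,NC_009905,1.69E-01,0.15,3.19E-01,6.38E-01,0.0009,24,9,12,645,3,73242
Schizophyllum commune,basidiomycetes,NC_003049,1.39E-01,0.32,4.59E-01,9.09E-01,0.002,27,0,0,1718,61,49704
Tilletia indica,basidiomycetes,NC_010651,8.97E-02,0.2,2.90E-01,5.74E-01,0.0008,24,0,0,568,52,65147
Trametes cingulata,basidiomycetes,NC_013933,3.00E-01,0.16,4.60E-01,9.11E-01,0.0006,25,26,26,1196,143,91500
Ustilago maydis,basidiomycetes,NC_008368,1.71E-01,0.14,3.11E-01,6.16E-01,0.0005,23,11,12,337,37,56814
Candida albicans,saccharomycetes1,NC_018046,2.37E-01,0.24,4.77E-01,1.22E+00,0.003,30,0,2,279,40,40420
Debaryomyces hansenii,saccharomycetes1,NC_010166,1.64E-01,0.19,3.54E-01,8.64E-01,0.004,25,4,4,389,20,29462
Dekkera bruxellensis,saccharomycetes1,NC_013147,2.15E-01,0.26,4.75E-01,1.16E+00,0.003,25,3,5,3968,939,76453
Millerozyma farinosa,saccharomycetes1,NC_013255,2.16E-01,0.2,4.16E-01,9.83E-01,0.004,25,11,14,710,31,39107
Ogataea angusta,saccharomycetes1,NC_014805,1.41E-01,0.4,5.41E-01,1.54E+00,0.004,26,6,6,944,46,41719
Pichia pastoris,saccharomycetes1,NC_015384,1.29E-01,0.21,3.39E-01,8.76E-01,0.002,25,3,6,1080,21,35683
Mycosphaerella graminicola,dothideomycetes,NC_010222,1.97E-01,0.16,3.57E-01,8.43E-01,0.0007,27,0,0,218,66,43964
Peltigera malacea,dothideomycetes,NC_016955,9.28E-02,0.2,2.93E-01,8.35E-01,0.001,26,17,20,468,31,62785
Phaeosphaeria nodorum,dothideomycetes,NC_009746,2.03E-01,0.18,3.83E-01,1.09E+00,0.0009,27,2,4,667,36,49761
Arthroderma obtusum,eurotiomycetes,NC_012830,7.66E-02,0.02,9.66E-02,2.48E-01,0.0007,25,1,1,325,14,24105
Microsporum canis,eurotiomycetes,NC_012832,7.66E-02,0.02,9.66E-02,2.38E-01,0.0007,25,1,1,344,10,23943
Paracoccidioides brasiliensis,eurotiomycetes,NC_007935,1.54E-01,0.24,3.94E-01,9.26E-01,0.001,25,3,13,552,175,71335
Penicillium marneffei,eurotiomycetes,NC_005256,2.38E-01,0.16,3.98E-01,9.19E-01,0.0007,28,9,11,303,16,35438
Beauveria bassiana,sordariomycetes,NC_017842,2.90E-02,0.002,3.10E-02,7.38E-02,0.0002,25,5,5,284,10,29961
Chaetomium thermophilum,sordariomycetes,NC_015893,1.45E-01,0.1,2.45E-01,6.29E-01,0.0008,28,3,3,927,113,127206
Cordyceps bassiana,sordariomycetes,NC_013145,5.53E-02,0.009,6.43E-02,1.65E-01,0.0005,24,4,5,295,10,32263
Fusarium oxysporum,sordariomycetes,NC_017930,5.37E-02,0.01,6.37E-02,1.66E-01,0.0006,25,1,2,298,1,34477
Gibberella zeae,sordariomycetes,NC_009493,5.67E-02,0.02,7.67E-02,2.00E-01,0.0006,28,33,35,529,48,95676
Lecanicillium muscarium,sordariomycetes,NC_004514,8.50E-02,0.05,1.35E-01,3.54E-01,0.002,25,1,1,241,9,24499
Metarhizium anisopliae,sordariomycetes,NC_008068,1.46E-01,0.12,2.66E-01,6.97E-01,0.001,24,1,1,220,2,24673
Podospora anserina,sordariomycetes,NC_001329,2.01E-01,0.09,2.91E-01,6.87E-01,0.0008,27,31,34,326,48,100314
Allomyces macrogynus,basals,NC_001715,1.97E-01,0.3,4.97E-01,7.44E-01,0.0004,25,10,28,219,14,57473
Rhizophydium sp. 136,basals,NC_003053,3.65E-01,1.2,1.56E+00,3.84E+00,0.002,7,1,1,809,13,68834
Schizosaccharomyces japonicus,other,NC_004332,5.08E-01,0.87,1.38E+00,3.38E+00,0.002,25,3,2,928,94,80059
Yarrowia lipolytica,other,NC_002659,2.00E-01,0.56,7.60E-01,1.76E+00,0.002,27,15,17,792,72,47916
Candida glabrata,saccharomycetes2,NC_004691,9.56E-02,0.09,1.86E-01,2.78E-01,0.001,23,3,3,797,68,20063
Kluyveromyces lactis,saccharomycetes2,NC_006077,3.49E-01,0.14,4.89E-01,1.09E+00,0.001,22,3,3,1190,279,40291
Nakaseomyces bacillisporus,saccharomycetes2,NC_012621,8.18E-02,0.2,2.82E-01,7.33E-01,0.003,23,0,0,7896,3791,107123
Vanderwaltozyma polyspora,saccharomycetes2,NC_009638,2.62E-01,0.17,4.32E-01,1.06E+00,0.002,23,0,0,1258,186,21684
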