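a49a70092763dadf4445143496c62f0bcfb4511a7f9e928183d487285bf7ea24  dikarya_species_stats.csv
7de1fb56ca9f3b854cae5f2d4963326425fd93605a5347399e2ffb0530c7b682  cluster_repeat_rearrangements.csv
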