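cluster,intergenic_repeats,intergenic_repeats_no_outliers,rearrangement_events
basidiomycetes,988,336,414
sordariomycetes,241,32,42
dothideomycetes,133,133,24
eurotiomycetes,215,40,22
saccharomycetes1,1097,158,156
saccharomycetes2,4324,254,22
basals,27,27,14
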