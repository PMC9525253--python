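id,cover,management,area_ha
MF,forest,managed,49.3
NF,forest,natural,38.2
MG,grassland,managed,3.9
NG,grassland,natural,14.8
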