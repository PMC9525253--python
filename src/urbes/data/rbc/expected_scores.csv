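compartment_id,shannon,carbon_storage,gross_sequestration,net_sequestration,avoided_runoff,oxygen_production,pollution_removal,uv_reduction,voc_emission,allergenicity,averaged_es_ed
MF,1.000,0.978,1.000,1.000,1.000,1.000,0.906,1.000,-1.000,-0.740,0.614
NF,0.999,1.000,0.993,0.991,0.741,0.992,1.000,0.957,-0.775,-1.000,0.590
MG,0.305,0.000,0.000,0.000,0.000,0.000,0.000,0.013,0.000,-0.287,0.003
NG,0.924,0.000,0.000,0.000,0.000,0.000,0.000,0.013,0.000,-0.396,0.054
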