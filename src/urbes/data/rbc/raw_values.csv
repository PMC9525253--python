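indicator_id,compartment_id,value,orientation,assessable
shannon,MF,3.48,ES,True
shannon,NF,3.47,ES,True
shannon,MG,1.06,ES,True
shannon,NG,3.21,ES,True
carbon_storage,MF,266.5,ES,True
carbon_storage,NF,272.6,ES,True
carbon_storage,MG,,ES,False
carbon_storage,NG,,ES,False
gross_sequestration,MF,7662.9,ES,True
gross_sequestration,NF,7612.8,ES,True
gross_sequestration,MG,,ES,False
gross_sequestration,NG,,ES,False
net_sequestration,MF,7057.86,ES,True
net_sequestration,NF,6995.8,ES,True
net_sequestration,MG,,ES,False
net_sequestration,NG,,ES,False
avoided_runoff,MF,3272.65,ES,True
avoided_runoff,NF,2425.17,ES,True
avoided_runoff,MG,,ES,False
avoided_runoff,NG,,ES,False
oxygen_production,MF,18820.9,ES,True
oxygen_production,NF,18665.5,ES,True
oxygen_production,MG,,ES,False
oxygen_production,NG,,ES,False
pollution_removal,MF,60.48,ES,True
pollution_removal,NF,66.75,ES,True
pollution_removal,MG,,ES,False
pollution_removal,NG,,ES,False
uv_reduction,MF,90.64,ES,True
uv_reduction,NF,86.73,ES,True
uv_reduction,MG,1.22,ES,True
uv_reduction,NG,1.22,ES,True
voc_emission,MF,9140.3,ED,True
voc_emission,NF,7084.9,ED,True
voc_emission,MG,,ED,False
voc_emission,NG,,ED,False
allergenicity,MF,0.56,ED,True
allergenicity,NF,0.75,ED,True
allergenicity,MG,,ED,False
allergenicity,NG,0.30,ED,True
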