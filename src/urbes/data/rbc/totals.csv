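quantity,compartment_id,value,units
carbon_storage_total,MF,11200,Mg
carbon_storage_total,NF,10400,Mg
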