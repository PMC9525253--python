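indicator_id,compartment_id,score
allergenicity,MF,-0.740
allergenicity,NF,-1.000
allergenicity,MG,-0.287
allergenicity,NG,-0.396
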