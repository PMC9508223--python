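organ,role,V_vasc_mL,V_int_mL,B_mL_per_h
blood_pool,blood_pool,12.0,,
LungPC,lung_pulmonary_circuit,2.0,1.0,0.0
LungBS,lung_blood_supply,0.4,0.5,10.0
Spleen,spleen,0.8,1.5,20.0
Stomach,mesenteric,0.6,1.0,25.0
S.Intestine,mesenteric,1.6,3.0,60.0
Liver,liver,1.8,4.0,35.0
LymphNodes,lymph_node,0.3,1.0,10.0
Skin,generic,0.5,6.0,40.0
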