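# Default circulatory wiring for the rat physiology table.
#
# portal_organs: splanchnic organs whose venous outflow drains into the
#   liver rather than returning directly to the heart.
# lymph_routing: "via_lymph_node" sends every organ's interstitial efflux
#   through the lymph-node interstitium before it returns to the heart;
#   a mapping {organ: direct_to_heart} overrides individual organs.
# lung_pc_flow_mode: "cardiac_output" sets the pulmonary-circuit blood flow
#   equal to total cardiac output (parallel-organ approximation of the
#   series lung); "table" keeps the value from the physiology table.
portal_organs: [Spleen, Stomach, S.Intestine]
lymph_routing: via_lymph_node
lung_pc_flow_mode: cardiac_output
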