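region_id,network
lh_bankssts,default
lh_caudalanteriorcingulate,ventral_attention
lh_caudalmiddlefrontal,dorsal_attention
lh_cuneus,visual
lh_entorhinal,limbic
lh_frontalpole,limbic
lh_fusiform,visual
lh_inferiorparietal,default
lh_inferiortemporal,default
lh_insula,ventral_attention
lh_isthmuscingulate,default
lh_lateraloccipital,visual
lh_lateralorbitofrontal,limbic
lh_lingual,visual
lh_medialorbitofrontal,limbic
lh_middletemporal,default
lh_paracentral,somatomotor
lh_parahippocampal,limbic
lh_parsopercularis,frontoparietal
lh_parsorbitalis,frontoparietal
lh_parstriangularis,frontoparietal
lh_pericalcarine,visual
lh_postcentral,somatomotor
lh_posteriorcingulate,default
lh_precentral,somatomotor
lh_precuneus,default
lh_rostralanteriorcingulate,default
lh_rostralmiddlefrontal,frontoparietal
lh_superiorfrontal,default
lh_superiorparietal,dorsal_attention
lh_superiortemporal,somatomotor
lh_supramarginal,ventral_attention
lh_temporalpole,limbic
lh_transversetemporal,somatomotor
rh_bankssts,default
rh_caudalanteriorcingulate,ventral_attention
rh_caudalmiddlefrontal,dorsal_attention
rh_cuneus,visual
rh_entorhinal,limbic
rh_frontalpole,limbic
rh_fusiform,visual
rh_inferiorparietal,default
rh_inferiortemporal,default
rh_insula,ventral_attention
rh_isthmuscingulate,default
rh_lateraloccipital,visual
rh_lateralorbitofrontal,limbic
rh_lingual,visual
rh_medialorbitofrontal,limbic
rh_middletemporal,default
rh_paracentral,somatomotor
rh_parahippocampal,limbic
rh_parsopercularis,frontoparietal
rh_parsorbitalis,frontoparietal
rh_parstriangularis,frontoparietal
rh_pericalcarine,visual
rh_postcentral,somatomotor
rh_posteriorcingulate,default
rh_precentral,somatomotor
rh_precuneus,default
rh_rostralanteriorcingulate,default
rh_rostralmiddlefrontal,frontoparietal
rh_superiorfrontal,default
rh_superiorparietal,dorsal_attention
rh_superiortemporal,somatomotor
rh_supramarginal,ventral_attention
rh_temporalpole,limbic
rh_transversetemporal,somatomotor
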