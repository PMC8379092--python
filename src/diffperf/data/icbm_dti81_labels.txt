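middle_cerebellar_peduncle
pontine_crossing_tract
genu_of_corpus_callosum
body_of_corpus_callosum
splenium_of_corpus_callosum
fornix_column_and_body
right_corticospinal_tract
left_corticospinal_tract
right_medial_lemniscus
left_medial_lemniscus
right_inferior_cerebellar_peduncle
left_inferior_cerebellar_peduncle
right_superior_cerebellar_peduncle
left_superior_cerebellar_peduncle
right_cerebral_peduncle
left_cerebral_peduncle
right_anterior_limb_of_internal_capsule
left_anterior_limb_of_internal_capsule
right_posterior_limb_of_internal_capsule
left_posterior_limb_of_internal_capsule
right_retrolenticular_part_of_internal_capsule
left_retrolenticular_part_of_internal_capsule
right_anterior_corona_radiata
left_anterior_corona_radiata
right_superior_corona_radiata
left_superior_corona_radiata
right_posterior_corona_radiata
left_posterior_corona_radiata
right_posterior_thalamic_radiation
left_posterior_thalamic_radiation
right_sagittal_stratum
left_sagittal_stratum
right_external_capsule
left_external_capsule
right_cingulum_cingulate_gyrus
left_cingulum_cingulate_gyrus
right_cingulum_hippocampus
left_cingulum_hippocampus
right_fornix_cres_stria_terminalis
left_fornix_cres_stria_terminalis
right_superior_longitudinal_fasciculus
left_superior_longitudinal_fasciculus
right_superior_fronto_occipital_fasciculus
left_superior_fronto_occipital_fasciculus
right_uncinate_fasciculus
left_uncinate_fasciculus
right_tapetum
left_tapetum
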