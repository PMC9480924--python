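name	lobe	hemisphere
Precentral_L	Frontal	L
Precentral_R	Frontal	R
Frontal_Sup_L	Frontal	L
Frontal_Sup_R	Frontal	R
Frontal_Sup_Orb_L	Frontal	L
Frontal_Sup_Orb_R	Frontal	R
Frontal_Mid_L	Frontal	L
Frontal_Mid_R	Frontal	R
Frontal_Mid_Orb_L	Frontal	L
Frontal_Mid_Orb_R	Frontal	R
Frontal_Inf_Oper_L	Frontal	L
Frontal_Inf_Oper_R	Frontal	R
Frontal_Inf_Tri_L	Frontal	L
Frontal_Inf_Tri_R	Frontal	R
Frontal_Inf_Orb_L	Frontal	L
Frontal_Inf_Orb_R	Frontal	R
Rolandic_Oper_L	Frontal	L
Rolandic_Oper_R	Frontal	R
Supp_Motor_Area_L	Frontal	L
Supp_Motor_Area_R	Frontal	R
Olfactory_L	Limbic	L
Olfactory_R	Limbic	R
Frontal_Sup_Medial_L	Frontal	L
Frontal_Sup_Medial_R	Frontal	R
Frontal_Med_Orb_L	Frontal	L
Frontal_Med_Orb_R	Frontal	R
Rectus_L	Frontal	L
Rectus_R	Frontal	R
Insula_L	Limbic	L
Insula_R	Limbic	R
Cingulum_Ant_L	Limbic	L
Cingulum_Ant_R	Limbic	R
Cingulum_Mid_L	Limbic	L
Cingulum_Mid_R	Limbic	R
Cingulum_Post_L	Limbic	L
Cingulum_Post_R	Limbic	R
Hippocampus_L	Limbic	L
Hippocampus_R	Limbic	R
ParaHippocampal_L	Limbic	L
ParaHippocampal_R	Limbic	R
Amygdala_L	Limbic	L
Amygdala_R	Limbic	R
Calcarine_L	Occipital	L
Calcarine_R	Occipital	R
Cuneus_L	Occipital	L
Cuneus_R	Occipital	R
Lingual_L	Occipital	L
Lingual_R	Occipital	R
Occipital_Sup_L	Occipital	L
Occipital_Sup_R	Occipital	R
Occipital_Mid_L	Occipital	L
Occipital_Mid_R	Occipital	R
Occipital_Inf_L	Occipital	L
Occipital_Inf_R	Occipital	R
Fusiform_L	Occipital	L
Fusiform_R	Occipital	R
Postcentral_L	Parietal	L
Postcentral_R	Parietal	R
Parietal_Sup_L	Parietal	L
Parietal_Sup_R	Parietal	R
Parietal_Inf_L	Parietal	L
Parietal_Inf_R	Parietal	R
SupraMarginal_L	Parietal	L
SupraMarginal_R	Parietal	R
Angular_L	Parietal	L
Angular_R	Parietal	R
Precuneus_L	Parietal	L
Precuneus_R	Parietal	R
Paracentral_Lobule_L	Parietal	L
Paracentral_Lobule_R	Parietal	R
Caudate_L	Limbic	L
Caudate_R	Limbic	R
Putamen_L	Limbic	L
Putamen_R	Limbic	R
Pallidum_L	Limbic	L
Pallidum_R	Limbic	R
Thalamus_L	Limbic	L
Thalamus_R	Limbic	R
Heschl_L	Temporal	L
Heschl_R	Temporal	R
Temporal_Sup_L	Temporal	L
Temporal_Sup_R	Temporal	R
Temporal_Pole_Sup_L	Temporal	L
Temporal_Pole_Sup_R	Temporal	R
Temporal_Mid_L	Temporal	L
Temporal_Mid_R	Temporal	R
Temporal_Pole_Mid_L	Temporal	L
Temporal_Pole_Mid_R	Temporal	R
Temporal_Inf_L	Temporal	L
Temporal_Inf_R	Temporal	R
Cerebelum_Crus1_L	Cerebellum	L
Cerebelum_Crus1_R	Cerebellum	R
Cerebelum_Crus2_L	Cerebellum	L
Cerebelum_Crus2_R	Cerebellum	R
Cerebelum_3_L	Cerebellum	L
Cerebelum_3_R	Cerebellum	R
Cerebelum_4_5_L	Cerebellum	L
Cerebelum_4_5_R	Cerebellum	R
Cerebelum_6_L	Cerebellum	L
Cerebelum_6_R	Cerebellum	R
Cerebelum_7b_L	Cerebellum	L
Cerebelum_7b_R	Cerebellum	R
Cerebelum_8_L	Cerebellum	L
Cerebelum_8_R	Cerebellum	R
Cerebelum_9_L	Cerebellum	L
Cerebelum_9_R	Cerebellum	R
Cerebelum_10_L	Cerebellum	L
Cerebelum_10_R	Cerebellum	R
Vermis_4_5	Cerebellum	V
Vermis_6	Cerebellum	V
Vermis_7	Cerebellum	V
Vermis_8	Cerebellum	V
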