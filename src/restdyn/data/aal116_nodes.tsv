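id	name	mni_x	mni_y	mni_z	source
AAL001	Precentral_L	0.0	0.0	0.0	AAL
AAL002	Precentral_R	0.0	0.0	0.0	AAL
AAL003	Frontal_Sup_L	0.0	0.0	0.0	AAL
AAL004	Frontal_Sup_R	0.0	0.0	0.0	AAL
AAL005	Frontal_Sup_Orb_L	0.0	0.0	0.0	AAL
AAL006	Frontal_Sup_Orb_R	0.0	0.0	0.0	AAL
AAL007	Frontal_Mid_L	0.0	0.0	0.0	AAL
AAL008	Frontal_Mid_R	0.0	0.0	0.0	AAL
AAL009	Frontal_Mid_Orb_L	0.0	0.0	0.0	AAL
AAL010	Frontal_Mid_Orb_R	0.0	0.0	0.0	AAL
AAL011	Frontal_Inf_Oper_L	0.0	0.0	0.0	AAL
AAL012	Frontal_Inf_Oper_R	0.0	0.0	0.0	AAL
AAL013	Frontal_Inf_Tri_L	0.0	0.0	0.0	AAL
AAL014	Frontal_Inf_Tri_R	0.0	0.0	0.0	AAL
AAL015	Frontal_Inf_Orb_L	0.0	0.0	0.0	AAL
AAL016	Frontal_Inf_Orb_R	0.0	0.0	0.0	AAL
AAL017	Rolandic_Oper_L	0.0	0.0	0.0	AAL
AAL018	Rolandic_Oper_R	0.0	0.0	0.0	AAL
AAL019	Supp_Motor_Area_L	0.0	0.0	0.0	AAL
AAL020	Supp_Motor_Area_R	0.0	0.0	0.0	AAL
AAL021	Olfactory_L	0.0	0.0	0.0	AAL
AAL022	Olfactory_R	0.0	0.0	0.0	AAL
AAL023	Frontal_Sup_Medial_L	0.0	0.0	0.0	AAL
AAL024	Frontal_Sup_Medial_R	0.0	0.0	0.0	AAL
AAL025	Frontal_Med_Orb_L	0.0	0.0	0.0	AAL
AAL026	Frontal_Med_Orb_R	0.0	0.0	0.0	AAL
AAL027	Rectus_L	0.0	0.0	0.0	AAL
AAL028	Rectus_R	0.0	0.0	0.0	AAL
AAL029	Insula_L	0.0	0.0	0.0	AAL
AAL030	Insula_R	0.0	0.0	0.0	AAL
AAL031	Cingulum_Ant_L	0.0	0.0	0.0	AAL
AAL032	Cingulum_Ant_R	0.0	0.0	0.0	AAL
AAL033	Cingulum_Mid_L	0.0	0.0	0.0	AAL
AAL034	Cingulum_Mid_R	0.0	0.0	0.0	AAL
AAL035	Cingulum_Post_L	0.0	0.0	0.0	AAL
AAL036	Cingulum_Post_R	0.0	0.0	0.0	AAL
AAL037	Hippocampus_L	0.0	0.0	0.0	AAL
AAL038	Hippocampus_R	0.0	0.0	0.0	AAL
AAL039	ParaHippocampal_L	0.0	0.0	0.0	AAL
AAL040	ParaHippocampal_R	0.0	0.0	0.0	AAL
AAL041	Amygdala_L	0.0	0.0	0.0	AAL
AAL042	Amygdala_R	0.0	0.0	0.0	AAL
AAL043	Calcarine_L	0.0	0.0	0.0	AAL
AAL044	Calcarine_R	0.0	0.0	0.0	AAL
AAL045	Cuneus_L	0.0	0.0	0.0	AAL
AAL046	Cuneus_R	0.0	0.0	0.0	AAL
AAL047	Lingual_L	0.0	0.0	0.0	AAL
AAL048	Lingual_R	0.0	0.0	0.0	AAL
AAL049	Occipital_Sup_L	0.0	0.0	0.0	AAL
AAL050	Occipital_Sup_R	0.0	0.0	0.0	AAL
AAL051	Occipital_Mid_L	0.0	0.0	0.0	AAL
AAL052	Occipital_Mid_R	0.0	0.0	0.0	AAL
AAL053	Occipital_Inf_L	0.0	0.0	0.0	AAL
AAL054	Occipital_Inf_R	0.0	0.0	0.0	AAL
AAL055	Fusiform_L	0.0	0.0	0.0	AAL
AAL056	Fusiform_R	0.0	0.0	0.0	AAL
AAL057	Postcentral_L	0.0	0.0	0.0	AAL
AAL058	Postcentral_R	0.0	0.0	0.0	AAL
AAL059	Parietal_Sup_L	0.0	0.0	0.0	AAL
AAL060	Parietal_Sup_R	0.0	0.0	0.0	AAL
AAL061	Parietal_Inf_L	0.0	0.0	0.0	AAL
AAL062	Parietal_Inf_R	0.0	0.0	0.0	AAL
AAL063	SupraMarginal_L	0.0	0.0	0.0	AAL
AAL064	SupraMarginal_R	0.0	0.0	0.0	AAL
AAL065	Angular_L	0.0	0.0	0.0	AAL
AAL066	Angular_R	0.0	0.0	0.0	AAL
AAL067	Precuneus_L	0.0	0.0	0.0	AAL
AAL068	Precuneus_R	0.0	0.0	0.0	AAL
AAL069	Paracentral_Lobule_L	0.0	0.0	0.0	AAL
AAL070	Paracentral_Lobule_R	0.0	0.0	0.0	AAL
AAL071	Caudate_L	0.0	0.0	0.0	AAL
AAL072	Caudate_R	0.0	0.0	0.0	AAL
AAL073	Putamen_L	0.0	0.0	0.0	AAL
AAL074	Putamen_R	0.0	0.0	0.0	AAL
AAL075	Pallidum_L	0.0	0.0	0.0	AAL
AAL076	Pallidum_R	0.0	0.0	0.0	AAL
AAL077	Thalamus_L	0.0	0.0	0.0	AAL
AAL078	Thalamus_R	0.0	0.0	0.0	AAL
AAL079	Heschl_L	0.0	0.0	0.0	AAL
AAL080	Heschl_R	0.0	0.0	0.0	AAL
AAL081	Temporal_Sup_L	0.0	0.0	0.0	AAL
AAL082	Temporal_Sup_R	0.0	0.0	0.0	AAL
AAL083	Temporal_Pole_Sup_L	0.0	0.0	0.0	AAL
AAL084	Temporal_Pole_Sup_R	0.0	0.0	0.0	AAL
AAL085	Temporal_Mid_L	0.0	0.0	0.0	AAL
AAL086	Temporal_Mid_R	0.0	0.0	0.0	AAL
AAL087	Temporal_Pole_Mid_L	0.0	0.0	0.0	AAL
AAL088	Temporal_Pole_Mid_R	0.0	0.0	0.0	AAL
AAL089	Temporal_Inf_L	0.0	0.0	0.0	AAL
AAL090	Temporal_Inf_R	0.0	0.0	0.0	AAL
AAL091	Cerebelum_Crus1_L	0.0	0.0	0.0	AAL
AAL092	Cerebelum_Crus1_R	0.0	0.0	0.0	AAL
AAL093	Cerebelum_Crus2_L	0.0	0.0	0.0	AAL
AAL094	Cerebelum_Crus2_R	0.0	0.0	0.0	AAL
AAL095	Cerebelum_3_L	0.0	0.0	0.0	AAL
AAL096	Cerebelum_3_R	0.0	0.0	0.0	AAL
AAL097	Cerebelum_4_5_L	0.0	0.0	0.0	AAL
AAL098	Cerebelum_4_5_R	0.0	0.0	0.0	AAL
AAL099	Cerebelum_6_L	0.0	0.0	0.0	AAL
AAL100	Cerebelum_6_R	0.0	0.0	0.0	AAL
AAL101	Cerebelum_7b_L	0.0	0.0	0.0	AAL
AAL102	Cerebelum_7b_R	0.0	0.0	0.0	AAL
AAL103	Cerebelum_8_L	0.0	0.0	0.0	AAL
AAL104	Cerebelum_8_R	0.0	0.0	0.0	AAL
AAL105	Cerebelum_9_L	0.0	0.0	0.0	AAL
AAL106	Cerebelum_9_R	0.0	0.0	0.0	AAL
AAL107	Cerebelum_10_L	0.0	0.0	0.0	AAL
AAL108	Cerebelum_10_R	0.0	0.0	0.0	AAL
AAL109	Vermis_1_2	0.0	0.0	0.0	AAL
AAL110	Vermis_3	0.0	0.0	0.0	AAL
AAL111	Vermis_4_5	0.0	0.0	0.0	AAL
AAL112	Vermis_6	0.0	0.0	0.0	AAL
AAL113	Vermis_7	0.0	0.0	0.0	AAL
AAL114	Vermis_8	0.0	0.0	0.0	AAL
AAL115	Vermis_9	0.0	0.0	0.0	AAL
AAL116	Vermis_10	0.0	0.0	0.0	AAL
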