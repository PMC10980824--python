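id	name	mni_x	mni_y	mni_z	source
MOT001	L_M1_hand	-38	-22	54	literature
MOT002	R_M1_hand	38	-22	54	literature
MOT003	L_SMA_proper	-6	-8	58	literature
MOT004	R_SMA_proper	6	-8	58	literature
MOT005	L_PMd	-26	-8	56	literature
MOT006	R_PMd	26	-8	56	literature
MOT007	L_Cerebellum_HV	-18	-52	-22	literature
MOT008	R_Cerebellum_HV	18	-52	-22	literature
MOT009	L_Putamen_post	-28	-6	2	literature
MOT010	R_Putamen_post	28	-6	2	literature
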