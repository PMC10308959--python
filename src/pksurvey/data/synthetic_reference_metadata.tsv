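id	leaf_label	group_label	ssn_group	phylum
ref_modular_cis-AT_00	modular cis-AT	cis-AT	cis-AT/iterative	Actinobacteria
ref_modular_cis-AT_01	modular cis-AT	cis-AT	cis-AT/iterative	Cyanobacteria
ref_modular_cis-AT_02	modular cis-AT	cis-AT	cis-AT/iterative	Proteobacteria
ref_modular_cis-AT_03	modular cis-AT	cis-AT	cis-AT/iterative	Actinobacteria
ref_modular_cis-AT_04	modular cis-AT	cis-AT	cis-AT/iterative	Cyanobacteria
ref_modular_cis-AT_05	modular cis-AT	cis-AT	cis-AT/iterative	Proteobacteria
ref_modular_cis-AT_06	modular cis-AT	cis-AT	cis-AT/iterative	Actinobacteria
ref_modular_cis-AT_07	modular cis-AT	cis-AT	cis-AT/iterative	Cyanobacteria
ref_cis-loading_module_00	cis-loading module	cis-AT	cis-AT/iterative	Actinobacteria
ref_cis-loading_module_01	cis-loading module	cis-AT	cis-AT/iterative	Proteobacteria
ref_cis-loading_module_02	cis-loading module	cis-AT	cis-AT/iterative	Actinobacteria
ref_cis-loading_module_03	cis-loading module	cis-AT	cis-AT/iterative	Proteobacteria
ref_cis-loading_module_04	cis-loading module	cis-AT	cis-AT/iterative	Actinobacteria
ref_cis-loading_module_05	cis-loading module	cis-AT	cis-AT/iterative	Proteobacteria
ref_cis-loading_module_06	cis-loading module	cis-AT	cis-AT/iterative	Actinobacteria
ref_cis-loading_module_07	cis-loading module	cis-AT	cis-AT/iterative	Proteobacteria
ref_olefin_synthase_00	olefin synthase	cis-AT	cis-AT/iterative	Cyanobacteria
ref_olefin_synthase_01	olefin synthase	cis-AT	cis-AT/iterative	Actinobacteria
ref_olefin_synthase_02	olefin synthase	cis-AT	cis-AT/iterative	Cyanobacteria
ref_olefin_synthase_03	olefin synthase	cis-AT	cis-AT/iterative	Actinobacteria
ref_olefin_synthase_04	olefin synthase	cis-AT	cis-AT/iterative	Cyanobacteria
ref_olefin_synthase_05	olefin synthase	cis-AT	cis-AT/iterative	Actinobacteria
ref_olefin_synthase_06	olefin synthase	cis-AT	cis-AT/iterative	Cyanobacteria
ref_olefin_synthase_07	olefin synthase	cis-AT	cis-AT/iterative	Actinobacteria
ref_iterative_aromatic_00	iterative aromatic	iterative cis-AT	cis-AT/iterative	Actinobacteria
ref_iterative_aromatic_01	iterative aromatic	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_aromatic_02	iterative aromatic	iterative cis-AT	cis-AT/iterative	Actinobacteria
ref_iterative_aromatic_03	iterative aromatic	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_aromatic_04	iterative aromatic	iterative cis-AT	cis-AT/iterative	Actinobacteria
ref_iterative_aromatic_05	iterative aromatic	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_aromatic_06	iterative aromatic	iterative cis-AT	cis-AT/iterative	Actinobacteria
ref_iterative_aromatic_07	iterative aromatic	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_PTM_00	iterative PTM	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_PTM_01	iterative PTM	iterative cis-AT	cis-AT/iterative	Verrucomicrobia
ref_iterative_PTM_02	iterative PTM	iterative cis-AT	cis-AT/iterative	Planctomycetes
ref_iterative_PTM_03	iterative PTM	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_PTM_04	iterative PTM	iterative cis-AT	cis-AT/iterative	Verrucomicrobia
ref_iterative_PTM_05	iterative PTM	iterative cis-AT	cis-AT/iterative	Planctomycetes
ref_iterative_PTM_06	iterative PTM	iterative cis-AT	cis-AT/iterative	Proteobacteria
ref_iterative_PTM_07	iterative PTM	iterative cis-AT	cis-AT/iterative	Verrucomicrobia
ref_trans-AT_00	trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_trans-AT_01	trans-AT	trans-AT	trans-AT	Firmicutes
ref_trans-AT_02	trans-AT	trans-AT	trans-AT	Proteobacteria
ref_trans-AT_03	trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_trans-AT_04	trans-AT	trans-AT	trans-AT	Firmicutes
ref_trans-AT_05	trans-AT	trans-AT	trans-AT	Proteobacteria
ref_trans-AT_06	trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_trans-AT_07	trans-AT	trans-AT	trans-AT	Firmicutes
ref_hybrid_trans-AT_00	hybrid trans-AT	trans-AT	trans-AT	Firmicutes
ref_hybrid_trans-AT_01	hybrid trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_hybrid_trans-AT_02	hybrid trans-AT	trans-AT	trans-AT	Firmicutes
ref_hybrid_trans-AT_03	hybrid trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_hybrid_trans-AT_04	hybrid trans-AT	trans-AT	trans-AT	Firmicutes
ref_hybrid_trans-AT_05	hybrid trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_hybrid_trans-AT_06	hybrid trans-AT	trans-AT	trans-AT	Firmicutes
ref_hybrid_trans-AT_07	hybrid trans-AT	trans-AT	trans-AT	Gammaproteobacteria
ref_hybrid_cis-AT_00	hybrid cis-AT	cis-AT	hybrid cis-AT	Cyanobacteria
ref_hybrid_cis-AT_01	hybrid cis-AT	cis-AT	hybrid cis-AT	Proteobacteria
ref_hybrid_cis-AT_02	hybrid cis-AT	cis-AT	hybrid cis-AT	Actinobacteria
ref_hybrid_cis-AT_03	hybrid cis-AT	cis-AT	hybrid cis-AT	Cyanobacteria
ref_hybrid_cis-AT_04	hybrid cis-AT	cis-AT	hybrid cis-AT	Proteobacteria
ref_hybrid_cis-AT_05	hybrid cis-AT	cis-AT	hybrid cis-AT	Actinobacteria
ref_hybrid_cis-AT_06	hybrid cis-AT	cis-AT	hybrid cis-AT	Cyanobacteria
ref_hybrid_cis-AT_07	hybrid cis-AT	cis-AT	hybrid cis-AT	Proteobacteria
ref_PUFA_00	PUFA	iterative cis-AT	PUFA	Deltaproteobacteria
ref_PUFA_01	PUFA	iterative cis-AT	PUFA	Gammaproteobacteria
ref_PUFA_02	PUFA	iterative cis-AT	PUFA	Deltaproteobacteria
ref_PUFA_03	PUFA	iterative cis-AT	PUFA	Gammaproteobacteria
ref_PUFA_04	PUFA	iterative cis-AT	PUFA	Deltaproteobacteria
ref_PUFA_05	PUFA	iterative cis-AT	PUFA	Gammaproteobacteria
ref_PUFA_06	PUFA	iterative cis-AT	PUFA	Deltaproteobacteria
ref_PUFA_07	PUFA	iterative cis-AT	PUFA	Gammaproteobacteria
ref_enediyne_00	enediyne	iterative cis-AT	enediyne	Actinobacteria
ref_enediyne_01	enediyne	iterative cis-AT	enediyne	Deltaproteobacteria
ref_enediyne_02	enediyne	iterative cis-AT	enediyne	Actinobacteria
ref_enediyne_03	enediyne	iterative cis-AT	enediyne	Deltaproteobacteria
ref_enediyne_04	enediyne	iterative cis-AT	enediyne	Actinobacteria
ref_enediyne_05	enediyne	iterative cis-AT	enediyne	Deltaproteobacteria
ref_enediyne_06	enediyne	iterative cis-AT	enediyne	Actinobacteria
ref_enediyne_07	enediyne	iterative cis-AT	enediyne	Deltaproteobacteria
ref_FAS_00	FAS	FAS	FAS	Proteobacteria
ref_FAS_01	FAS	FAS	FAS	Firmicutes
ref_FAS_02	FAS	FAS	FAS	Proteobacteria
ref_FAS_03	FAS	FAS	FAS	Firmicutes
ref_FAS_04	FAS	FAS	FAS	Proteobacteria
ref_FAS_05	FAS	FAS	FAS	Firmicutes
ref_FAS_06	FAS	FAS	FAS	Proteobacteria
ref_FAS_07	FAS	FAS	FAS	Firmicutes
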