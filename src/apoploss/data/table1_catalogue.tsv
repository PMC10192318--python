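# Curated catalogue of apoptotic-actor homologs per taxon group.
# Columns: taxon, species, category, protein_id, status, flags (comma-sep, optional)
# status: intact | pseudogene | absent_marker
taxon	species	category	protein_id	status	flags
Hydra	Hydra_vulgaris	caspase	HyCaspA	intact
Hydra	Hydra_vulgaris	caspase	HyCaspB	intact
Hydra	Hydra_vulgaris	caspase	HyCaspC	intact
Hydra	Hydra_vulgaris	caspase	HyCaspD	intact
Hydra	Hydra_vulgaris	caspase	HyCaspE	intact
Hydra	Hydra_vulgaris	caspase	HyCaspF	intact
Hydra	Hydra_vulgaris	caspase	HyCaspG	intact
Hydra	Hydra_vulgaris	caspase	HyCaspH	intact
Hydra	Hydra_vulgaris	caspase	HyCaspI	intact
Hydra	Hydra_vulgaris	caspase	HyCaspL	intact
Hydra	Hydra_vulgaris	caspase	HyCaspM	intact
Hydra	Hydra_vulgaris	caspase	HyCARDCasp-1	intact	initiator_card
Hydra	Hydra_vulgaris	caspase	HyCARDCasp-2	intact	initiator_card
Hydra	Hydra_vulgaris	caspase	HyDEDCasp	intact	initiator_ded
Hydra	Hydra_vulgaris	caspase	HyDDCasp	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-1	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-2	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-3	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-4	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-5	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-6	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBcl-2-like-7	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBak-like-1	intact
Hydra	Hydra_vulgaris	bcl2_multidomain	HyBak-like-2	intact
Hydra	Hydra_vulgaris	bh3_only	HyBH3-only-1	intact
Hydra	Hydra_vulgaris	bh3_only	HyBH3-only-2	intact
Hydra	Hydra_vulgaris	bh3_only	HyBH3-only-3	intact
Hydra	Hydra_vulgaris	bh3_only	HyBH3-only-4	intact
Hydra	Hydra_vulgaris	death_receptor	HyTNFR-like	intact
Hydra	Hydra_vulgaris	adaptor_protein	HyFADD	intact
Hydra	Hydra_vulgaris	iap	HyIAP	intact
Hydra	Hydra_vulgaris	apaf1	HyAPAF-1	intact
Hydra	Hydra_vulgaris	p53	Hyp53	intact
Hydra	Hydra_vulgaris	cytochrome_c	HyCytC	intact
Hydra	Hydra_vulgaris	calpain	HyCalpain-5	intact
Hydra	Hydra_vulgaris	calpain	HyCalpain-7	intact
Hydra	Hydra_vulgaris	calpain	HyCalpain-9	intact
Polypodium	Polypodium_hydriforme	caspase	PolCasp	intact
Polypodium	Polypodium_hydriforme	caspase	PolCARDCasp	intact	initiator_card
Polypodium	Polypodium_hydriforme	bcl2_multidomain	PolBCL-2-1	intact
Polypodium	Polypodium_hydriforme	bcl2_multidomain	PolBCL-2-2	intact
Polypodium	Polypodium_hydriforme	bcl2_multidomain	PolBOK	intact
Polypodium	Polypodium_hydriforme	bcl2_multidomain	PolBAK-1	intact
Polypodium	Polypodium_hydriforme	bcl2_multidomain	PolBAK-2	intact
Polypodium	Polypodium_hydriforme	iap	PolIAP	intact
Polypodium	Polypodium_hydriforme	apaf1	PolAPAF-1	intact
Polypodium	Polypodium_hydriforme	p53	PolP53	intact
Polypodium	Polypodium_hydriforme	cytochrome_c	PolCytC	intact
Polypodium	Polypodium_hydriforme	calpain	PolCalp-5	intact
Polypodium	Polypodium_hydriforme	calpain	PolCalp-7	intact
Polypodium	Polypodium_hydriforme	calpain	PolClassCalp-1	intact	classical
Polypodium	Polypodium_hydriforme	calpain	PolClassCalp-2	intact	classical
Malacosporea	Buddenbrockia_plumatellae	caspase	BuddCasp	intact
Malacosporea	Buddenbrockia_plumatellae	cytochrome_c	BuddCytC	intact
Malacosporea	Tetracapsuloides_bryosalmonae	cytochrome_c	TetrCytC	intact
Myxosporea	Myxobolus_pronini	cytochrome_c	MpCytC	intact
Myxosporea	Thelohanellus_kitauei	cytochrome_c	TkCytC	intact
Myxosporea	Myxobolus_honghuensis	cytochrome_c	MhCytC	intact
Myxosporea	Enteromyxum_leei	cytochrome_c	ElCytC	pseudogene
Myxosporea	Sphaeromyxa_zaharoni	cytochrome_c	SzCytC	pseudogene
Myxosporea	Kudoa_iwatai	cytochrome_c	KiCytC	pseudogene
Myxosporea	Henneguya_salminicola	cytochrome_c	HsalCytC-absent	absent_marker
Myxosporea	Myxobolus_squamalis	cytochrome_c	MsqCytC-absent	absent_marker
Caenorhabditis_elegans	Caenorhabditis_elegans	caspase	Ced-3	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	caspase	Csp-1	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	caspase	Csp-2	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	bcl2_multidomain	Ced-9	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	bh3_only	Egl-1	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	bh3_only	Ced-13	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	apaf1	Ced-4	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	p53	Cep-1	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	cytochrome_c	CPS-6	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	cytochrome_c	WAH-1	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	calpain	CLP-1	intact
Caenorhabditis_elegans	Caenorhabditis_elegans	calpain	TRA-3	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-1	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-2	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-3	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-4	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-5	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-6	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-7	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-8	intact	initiator_ded
Homo_sapiens	Homo_sapiens	caspase	Caspase-9	intact	initiator_card
Homo_sapiens	Homo_sapiens	caspase	Caspase-10	intact	initiator_ded
Homo_sapiens	Homo_sapiens	caspase	Caspase-12	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-13	intact
Homo_sapiens	Homo_sapiens	caspase	Caspase-14	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bcl-2	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bcl-xL	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bcl-W	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Mcl-1	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bcl-B	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bcl-2A1	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bax	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bak	intact
Homo_sapiens	Homo_sapiens	bcl2_multidomain	Bok	intact
Homo_sapiens	Homo_sapiens	bh3_only	Bid	intact
Homo_sapiens	Homo_sapiens	bh3_only	Bmf	intact
Homo_sapiens	Homo_sapiens	bh3_only	NOXA	intact
Homo_sapiens	Homo_sapiens	bh3_only	PUMA	intact
Homo_sapiens	Homo_sapiens	bh3_only	Bad	intact
Homo_sapiens	Homo_sapiens	bh3_only	Bim	intact
Homo_sapiens	Homo_sapiens	bh3_only	Bik	intact
Homo_sapiens	Homo_sapiens	bh3_only	Hrk	intact
Homo_sapiens	Homo_sapiens	death_receptor	TNF-R	intact
Homo_sapiens	Homo_sapiens	adaptor_protein	FADD	intact
Homo_sapiens	Homo_sapiens	adaptor_protein	TRADD	intact
Homo_sapiens	Homo_sapiens	iap	XIAP	intact
Homo_sapiens	Homo_sapiens	iap	NAIP	intact
Homo_sapiens	Homo_sapiens	iap	c-IAP1	intact
Homo_sapiens	Homo_sapiens	iap	c-IAP2	intact
Homo_sapiens	Homo_sapiens	apaf1	APAF-1	intact
Homo_sapiens	Homo_sapiens	p53	p53	intact
Homo_sapiens	Homo_sapiens	cytochrome_c	CytC	intact
Homo_sapiens	Homo_sapiens	calpain	Calpain-5	intact
Homo_sapiens	Homo_sapiens	calpain	Calpain-7	intact
Homo_sapiens	Homo_sapiens	calpain	Calpain-9	intact
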