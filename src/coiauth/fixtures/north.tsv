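sample_code	processed_replicates	retail_type	menu_label	declared_species	identified_species	genbank_accession	blast_accession	bold_id	identity_pct	misdescribed	declared_unlisted
MIL1B	3	restaurant	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Dicentrarchus labrax	MW714726	KP330301	GBMIN94166-17	99.69	0	0
MIL1T	3	restaurant	tuna	Thunnus thynnus	Thunnus albacares	MW714727	MH638785	ANGBF54814-19	99.54	1	0
MIL2B	1	takeaway	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Dicentrarchus labrax	MW714728	KY176457	GBMIN121550-17	99.37	0	0
MIL2T	3	takeaway	tuna	Thunnus thynnus	Thunnus albacares	MW714729	MH638777	ANGBF54806-19	98.47	1	0
MIL3B	3	takeaway	sea bream	Sparus aurata/Dicentrarchus labrax	Dicentrarchus labrax	MW714730	KP330301	GBMIN94165-17	98.74	0	0
MIL4B	3	takeaway	common bass	Sparus aurata/Dicentrarchus labrax	Sparus aurata	MW714731	MF438138	ANGBF45411-19	99.54	0	0
CES1B	3	takeaway	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714732	KP330300	GBMIN94165-17	99.06	0	0
DAL1B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714733	JQ623999	DNATR096-12	99.24	0	0
DAL1T	3	restaurant	tuna	Thunnus thynnus	Thunnus albacares	MW714734	MH638785	ANGBF54814-19	99.24	1	0
DAL1E	3	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys oxycephalus	MW714735	KX769042	GBMIN125981-17	99.02	0	1
VI1T	3	restaurant	tuna	Thunnus thynnus	Thunnus thynnus	MW714736	KP975912	FCSF387-14	98.92	0	0
VI1B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714737	KC501553	DNATR1582-13	98.78	0	0
VI1E	3	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714738	JQ842898	TOBA086-09	99.52	0	1
FC1B	3	takeaway	sea bream	Sparus aurata	Seriola lalandi	MW714739	MH211123	GBMNA18700-19	99.39	1	0
FC1T	3	takeaway	maguro Yaki (red tuna)	Thunnus thynnus	Thunnus thynnus	MW714740	KC501694	DNATR1720-13	99.39	0	0
FC2B	1	takeaway	sea bream	Sparus aurata	Sparus aurata	MW714741	MF438138	ANGBF45411-19	99.69	0	0
UD1B	3	restaurant	kajiki roll (swordfish)	Xiphias gladius	Xiphias gladius	MW714742	MK295657	ANGBF51916-19	99.38	0	0
UD1T	2	restaurant	tuna	Thunnus thynnus	Thunnus obesus	MW714743	GU451774	GBGCA1353-13	99.08	1	0
UD1E	3	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Mallotus villosus	MW714744	HM421773	DSFAL635-09	99.39	1	1
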