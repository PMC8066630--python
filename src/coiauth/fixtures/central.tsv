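sample_code	processed_replicates	retail_type	menu_label	declared_species	identified_species	genbank_accession	blast_accession	bold_id	identity_pct	misdescribed	declared_unlisted
FIR1B	3	takeaway	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714657	KP330300	GBMIN94165-17	99.21	0	0
FIR1T	3	takeaway	tuna	Thunnus thynnus	Thunnus albacares	MW714658	MH638777	ANGBF54806-19	99.85	1	0
FIR1E	3	takeaway	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714659	JQ842898	TOBA9086	99.52	0	1
PER1B	3	restaurant	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Sparus aurata	MW714660	MF438138	ANGBF45411-19	99.54	0	0
PER1T	3	restaurant	tuna	Thunnus thynnus	Thunnus albacares	MW714661	MH638785	ANGBF54814-19	99.39	1	0
PER1E	1	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714662	JQ842898	TOBA9086	99.35	0	1
PER2B	3	takeaway	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Dicentrarchus labrax	MW714663	KP330301	GBMIN94166-17	99.21	0	0
ORV1B	3	takeaway	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714664	KP330301	GBMIN94166-17	98.58	0	0
ORV1T	2	takeaway	tuna	Thunnus thynnus	Thunnus albacares	MW714665	MH638785	ANGBF54814-19	98.17	1	0
ORV1E	3	takeaway	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714666	JQ842898	TOBA086-09	99.52	0	1
ORV2B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714667	KC501553	DNATR1582-13	98.47	0	0
TER1B	3	takeaway	sea bream	Sparus aurata	Sparus aurata	MW714668	KC501557	DNATR1596-13	99.39	0	0
TER1T	3	takeaway	tuna	Thunnus thynnus	Thunnus orientalis	MW714669	JN097817	GBGCA1390-13	99.70	1	0
TER1E	3	takeaway	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714670	JQ842898	TOBA9086	99.52	0	1
PE1B	3	restaurant	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714671	KP330301	GBMIN94166-17	98.58	0	0
PE1T	3	restaurant	tuna	Thunnus thynnus	Thunnus albacares	MW714672	MH638785	ANGBF54814-19	98.92	1	0
PE1E	1	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys coromandelensis	MW714673	KX379460	ANGBF32076-19	98.73	0	1
RO1B	3	restaurant	sea bream	Sparus aurata	Seriola lalandi	MW714674	MF069453	ANGBF17684-19	99.24	1	0
RO1T	3	restaurant	tuna	Thunnus thynnus	Thunnus albacares	MW714675	HM007768	ANGBF7098-12	99.39	1	0
RO1E	1	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Mallotus villosus	MW714676	FJ205579	GBGC7486-09	99.23	1	1
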