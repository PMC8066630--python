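sample_code	processed_replicates	retail_type	menu_label	declared_species	identified_species	genbank_accession	blast_accession	bold_id	identity_pct	misdescribed	declared_unlisted
CAT1B	3	restaurant	sea bream or common bass	Sparus aurata	Sparus aurata	MW714949	KC501553	DNATR1582-13	99.08	0	0
CAT1T	3	restaurant	Tuna	Thunnus thynnus	Thunnus albacares	MW714950	MH638785	ANGBF54814-19	99.54	1	0
CAT1E	3	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Mallotus villosus	MW714951	FJ205579	GBGC7486-09	99.39	1	1
CAT3B	3	restaurant	sea bream or common bass	Sparus aurata	Xiphias gladius	MW714952	JN049558	ANGBF7251-12	99.54	1	0
GE1B	3	restaurant	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714953	KP330301	GBMIN94166-17	99.53	0	0
GE1T	3	restaurant	Tuna	Thunnus thynnus	Thunnus albacares	MW714954	MH638785	ANGBF54814-19	99.08	1	0
GE1E	3	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Hirundichthys affinis	MW714955	JQ842898	TOBA086-09	99.52	0	1
GE2B	3	restaurant	common bass	Dicentrarchus labrax	Dicentrarchus labrax	MW714956	KP330301	GBMIN94166-17	99.53	0	0
ME1B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714957	MF438138	ANGBF45411-19	99.85	0	0
ME1T	3	restaurant	Tuna	Thunnus thynnus	Thunnus albacares	MW714958	MH638762	ANGBF54791-19	98.93	1	0
ME1E	3	restaurant	lumpfish roe	Cyclopterus lumpus	Cyclopterus lumpus	MW714959	MG421634	TZAIC166-05	99.54	0	0
ME2B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714960	MF438138	ANGBF45411-19	99.39	0	0
ME2E	2	restaurant	Ikura	salmon eggs	Oncorhynchus keta	MW714961	LC094477	ANGBF41103-19	98.93	0	0
RC1B	3	takeaway	Anago	Anguilla sp	Anguilla rostrata	MW714962	KX459333	SERCA165-12	98.31	0	0
RC1T	3	takeaway	Tuna	Thunnus thynnus	Thunnus albacares	MW714963	MH638785	ANGBF54814-19	99.39	1	0
RC1E	2	takeaway	Ikura	salmon eggs	Oncorhynchus keta	MW714964	LC094477	ANGBF41103-19	99.54	0	0
RC2E	2	takeaway	lumpfish roe	Cyclopterus lumpus	Cyclopterus lumpus	MW714965	MG421634	TZAIC166-05	99.07	0	0
LE1B	3	restaurant	sea bream	Sparus aurata	Sparus aurata	MW714966	MF438138	ANGBF45411-19	98.93	0	0
LE1E	1	restaurant	tobiko/flying fish egg	Hirundichthys affinis	Mallotus villosus	MW714967	FJ205579	GBGC7486-09	99.39	1	1
NA1B	3	takeaway	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Sparus aurata	MW714968	KC501554	DNATR1599-13	99.24	0	0
NA2B	3	takeaway	sea bream or common bass	Sparus aurata/Dicentrarchus labrax	Pomatomus saltatrix	MW714969	KC501113	DNATR1143-13	99.39	1	0
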