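flux_id	enzyme_id	mediator_id	value	printed_total
r2	r10	G6P_in	6.68	-1.63
r2	r10	F6P_in	4.09	-1.63
r2	r10	6PG_in	-12.40	-1.63
r2	r2	G6P_in	-0.61	0.11
r2	r2	F6P_in	-0.52	0.11
r2	r2	6PG_in	0.24	0.11
r18	r41	NAD_in	-0.043	0.718
r18	r41	PYR_in	0.954	0.718
r18	r41	LAC_in	-0.017	0.718
r18	r41	NADH_in	-0.176	0.718
r43	r22	PYR_in	0.069	1.287
r43	r22	NADP_in	0.579	1.287
r43	r22	MAL_in	-0.398	1.287
r43	r22	NADPH_in	1.037	1.287
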