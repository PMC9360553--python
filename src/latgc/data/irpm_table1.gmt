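IRPM_positive	immune-infiltration positively correlated marker genes	DOK2	ITGB2	LAPTM5	CD86	CD53	WAS	PLEK	AIF1	MYO1F	CYTH4	ABI3	LSP1	SPI1	CD4	MS4A6A	IL10RA	CYBB	HCST	C1QA	NCKAP1L	C1QB	C1QC	TNFAIP8L2	MNDA	SRGN	SLAMF8	CD84	GMFG	MYO1G	GIMAP4	C3AR1	LILRB1	LST1	HCLS1	HAVCR2
IRPM_negative	immune-infiltration negatively correlated marker genes	GGH	SQLE	F11R	HMGCS1	TRIP13	MAP7	NUF2	SRP9	PERP	EFNA1	TOP2A	TBCE
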