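category	autoantigen	uniprot	gene
Higher in PL (> 45%)	C-terminal binding protein 1	Q13363	CTBP1
Higher in PL (> 45%)	Guanine nucleotide binding protein (G protein), alpha 13	Q14344	GNA13
Higher in PL (> 45%)	Presenilin associated, rhomboid-like protein	Q9H300	PARL
Higher in PL (> 45%)	Trans-2,3-enoyl-CoA reductase	Q9NZ01	GPSN2
Higher in PL (> 45%)	Cas-Br-M (murine) ecotropic retroviral transforming sequence b	Q13191	CBLB
Higher in PL (> 45%)	Abhydrolase domain containing 16A	O95870	BAT5
Higher in PL (> 45%)	Tubulin, gamma complex associated protein 3	Q96CW5	TUBGCP3
Higher in PL (> 45%)	Modulator of apoptosis 1	Q96BY2	MOAP1
Higher in PL (> 45%)	Family with sequence similarity 76, member B	Q5HYJ3	FAM76B
Higher in PL (> 45%)	Thyroid hormone receptor, alpha	P10827	THRA
Higher in PL (> 45%)	Apolipoprotein A-II	P02652	APOA2
Higher in PL (> 45%)	Eyes absent homolog 2 (Drosophila)	O00167	EYA2
Higher in PL (> 45%)	IL-6 receptor	P08887	IL6R
Higher in PL (> 45%)	G protein-coupled receptor 153	Q6NV75	GPR153
Higher in PL (> 45%)	Histone deacetylase 3	O15379	HDAC3
Higher in PL (> 45%)	Actin related protein M1	Q9BYD9	ARPM1
Higher in PL (> 45%)	Natural killer cell group 7 sequence	Q16617	NKG7
Higher in PL (> 45%)	Mitogen-activated protein kinase kinase 7	O14733	MAP2K7
Higher in PL (> 45%)	Ubiquitin-conjugating enzyme E2A (RAD6 homolog)	P49459	UBE2A
Higher in PL (> 45%)	v-kit Hardy-Zuckerman 4 feline sarcoma viral oncogene homolog	P10721	KIT
Higher in PL (> 45%)	Pleckstrin homology domain containing, family O member 1	Q53GL0	PLEKHO1
Higher in PL (> 45%)	Adaptor-related protein complex 1, sigma 1 subunit	P61966	AP1S1
Higher in PL (> 45%)	neuregulin 1	Q02297	NRG1
Higher in PL (> 45%)	Peroxisomal biogenesis factor 5	P50542	PEX5
Higher in PL (> 45%)	Nuclear receptor subfamily 6, group A, member 1	Q15406	NR6A1
Higher in PL (> 45%)	Serine/threonine kinase 10	O94804	STK10
Higher in PL (> 45%)	Eukaryotic translation initiation factor 1	P41567	EIF1
Higher in PL (> 45%)	Zinc finger protein 36, C3H type-like 2	P47974	ZFP36L2
Higher in PL (> 45%)	Cartilage oligomeric matrix protein	P49747	COMP
Higher in SF (> 45%)	Actinin, alpha 1	A1L0V1	ACTN1
Similar levels in PL and SF (< 10%)	Protein phosphatase 2, catalytic subunit, beta isozyme	P62714	PPP2CB
Similar levels in PL and SF (< 10%)	Peroxisomal biogenesis factor 10	O60683	PEX10
Similar levels in PL and SF (< 10%)	mitogen-activated protein kinase kinase kinase 7	O43318	MAP3K7
Similar levels in PL and SF (< 10%)	3-Hydroxy-3-methylglutaryl-CoA synthase 1	Q01581	HMGCS1
Similar levels in PL and SF (< 10%)	TNF receptor-associated protein 1	Q12931	TRAP1
Similar levels in PL and SF (< 10%)	Troponin C type 1 (slow)	P63316	TNNC1
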