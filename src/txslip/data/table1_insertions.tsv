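source_id	replicate	location	upstream	event_seq	downstream	kind
tab1-r01	1	1001	GCCGCTGGCGC	GCCGCTGGCGC	AATGGATAG	insertion
tab1-r02	1	1002	TATTTATTT	ATTT	CGCCCTGCC	insertion
tab1-r03	1	1003	GTGATGATG	ATG	TATAACCGG	insertion
tab1-r04	1	1004	AGAAGAAGA	AGA	TAAAAACAG	insertion
tab1-r05	1	1005	TTCTTCTTC	TTC	GCGAAGCGT	insertion
tab1-r06	1	1006	CTCTTCTTC	TTC	CAGCGTCGG	insertion
tab1-r07	1	1007	CTTGAGCCG	CCG	TCGTCGTGG	insertion
tab1-r08	1	1008	TTCTTCTTC	TTC	AACACCGAC	insertion
tab1-r09	1	1009	AACAACAAC	AAC	CGATGAACT	insertion
tab1-r10	1	1010	CGGTCTGGA	AG	CAAAGGCAC	insertion
tab1-r11	1	1011	CGGCGGTTA	A	TTTTTTTGC	insertion
tab1-r12	1	1012	TCGAAGAAC	C	GCGTTAAGA	insertion
tab1-r13	1	1013	TCCGTTCTA	A	CAAACATTT	insertion
tab1-r14	1	1014	GAACAGGCG	G	AAAAAAGTG	insertion
tab1-r15	1	1015	CTGAAAGAA	A	GCGGCAGAA	insertion
tab1-r16	1	1016	TTCGTAGAA	A	GCTGAGTAA	insertion
tab1-r17	1	1017	CATACCACC	T	ATCGTTAAG	insertion
tab1-r18	1	1018	CTGGCAGAA	G	ACGTTATCC	insertion
tab1-r19	1	1019	ACTGGCGGC	A	GCAAACCGG	insertion
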