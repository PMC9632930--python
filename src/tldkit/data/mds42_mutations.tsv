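gene_or_locus	mutation	function
atpF	Q85* (G→A)	F0 sector of membrane-bound ATP synthase, subunit b
gidA ← / ← mioC	intergenic (-239/+140) (T→A)	mioC and gidA are the well-conserved genes surrounding the E. coli replication origin, oriC
glnH	L5F (TTA→TTT)	glutamine transporter subunit
glnH	V4V (GTA→GTT)	glutamine transporter subunit
lsrF	I153L (A→C)	predicted aldolase
ptsH	A20T (GCC→ACC)	phosphohistidinoprotein-hexose phosphotransferase component of PTS system (Hpr)
recJ	Δ1 bp coding (1191/1734 nt)	ssDNA exonuclease, 5'->3'-specific
speB	I59F (T→A)	agmatinase
tdcD	F146S (TTC→TCC)	propionate kinase/acetate kinase C, anaerobic
ycjW	T4A (ACT→GCT)	predicted DNA-binding transcriptional regulator involved in the bacterial stringent response
ygeG → / → ygeH	intergenic (+197/-138) (A→T)	predicted chaperone/predicted transcriptional regulator
yihU ← / → yihV	intergenic (-102/-66) (G→T)	predicted oxidoreductase with NAD(P)-binding Rossmann-fold domain/predicted sugar kinase
yjeP	A853T (GCG→ACG)	predicted mechanosensitive channel
yjeP	V794A (GTC→GCC)	predicted mechanosensitive channel
yraK	I237N	part of putative chaperone-usher fimbrial operon
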