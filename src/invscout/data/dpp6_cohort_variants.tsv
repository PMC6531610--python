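patient	diagnosis	aao	aai	cdna	protein	domain
DR1149	FTD	77	79	c.14C>A	p.A5D	IC_Is3
DR1143	AD	58	67	c.58G>A	p.A20T	IC_Is1
DR1143	AD	58	67	c.109G>A	p.G37S	IC_Is1
DR1350	FTD-PPA	74		c.109G>A	p.G37S	IC_Is1
DR40	FTD	44	50	c.140G>T	p.R47L	IC_Is1
DR623	FTD		71	c.140G>T	p.R47L	IC_Is1
DR1144	AD	59	61	c.160C>G	p.R54G	IC_Is1
DR807	FTD	65		c.160C>G	p.R54G	IC_Is1
DR1351	AD	56		c.160C>G	p.R54G	IC_Is1
DR1352	AD	55		c.160C>G	p.R54G	IC_Is1
DR1147	FTD	65	65	c.182_187dup	p.G61_G62dup	IC_Is1
DR1145	FTD-ALS	76		c.235_236dupG	p.E79Gfs*9	IC_Is1
DR1153	FTD	67		c.331G>A	p.V111I	TM
DR1151	FTD	63		c.383A>G	p.K128R	EC
DR1198	FTD	52		c.622G>C	p.E208Q	EC
DR1150	PPA	80	81	c.685C>A	p.P229T	EC
DR1154	FTD		67	c.688C>T	p.Q230*	EC
DR1155	AD	68	68	c.821G>A	p.R274H	EC
DR1156	AD	53		c.965G>A	p.R322H	EC
DR1289	AD	59		c.1070A>G	p.H357R	EC
DR414	PPA	57	59	c.1526C>G	p.P509R	EC
DR1152	FTD-ALS	75	75	c.1705G>A	p.D569N	EC
DR1353	FTD	65		c.1711A>C	p.K571Q	EC
DR1354	AD	63		c.1711A>C	p.K571Q	EC
DR114	FTD	67	68	c.1964C>T	p.A655V	EC
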