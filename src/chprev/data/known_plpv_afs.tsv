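gene	hgvs_c	hgvs_p	consequence	AF_GLOBAL	AF_AFR	AF_AMR	AF_ASJ	AF_EAS	AF_FIN	AF_NFE	AF_SAS
TPO	c.483-1G>C		splice_site	0.00013	0.00133	0.00004	0	0	0	0.00001	0
TPO	c.1184_1187dupGCCG	p.Ala397ProfsTer76	frameshift	0.00053	0	0.00037	0	0	0.00156	0.00092	0
TPO	c.1978C>G	p.Gln660Glu	missense	0.00030	0.00008	0.00119	0	0	0	0.00023	0
TPO	c.2268dupT	p.Glu757Ter	frameshift	0.00012	0	0	0	0.00165	0	0	0
TG	c.886C>T	p.Arg296Ter	nonsense	0.00035	0.00028	0.00059	0.00106	0	0.00004	0.00042	0.00003
TG	c.1963C>T	p.Gln655Ter	nonsense	0.00013	0	0	0	0	0.00140	0.00002	0
TG	c.5184C>A	p.Cys1728Ter	nonsense	0.00010	0	0.00003	0.00188	0	0	0.00003	0
IYD	c.315_317delCAT	p.Phe105_Ile106delinsLeu	inframe_indel	0.00011	0.00008	0	0	0	0	0.00022	0
DUOXA2	c.413dupA	p.Tyr138Ter	frameshift	0.00023	0	0	0	0.00333	0	0	0
DUOXA2	c.738C>G	p.Tyr246Ter	nonsense	0.00014	0	0	0	0.00186	0	0.00001	0
DUOX2	c.4524+1dupG		splice_site	0.00011	0.00126	0.00003	0	0	0	0	0
DUOX2	c.3693+1G>T		splice_site	0.00011	0	0	0	0.00160	0	0	0
DUOX2	c.3329G>A	p.Arg1110Gln	missense	0.00019	0	0.00003	0	0.00251	0	0.00002	0
DUOX2	c.3155G>A	p.Cys1052Tyr	missense	0.00128	0.00012	0.00014	0.00010	0	0.00629	0.00140	0
DUOX2	c.2895_2898delGTTC	p.Phe966SerfsTer29	frameshift	0.00290	0.00056	0.00158	0	0	0.01139	0.00290	0.00213
DUOX2	c.1588A>T	p.Lys530Ter	nonsense	0.00063	0	0	0	0.00882	0	0	0
DUOX2	c.1516G>A	p.Asp506Asn	missense	0.00026	0.00004	0.00003	0	0	0.00040	0.00047	0
DUOX2	c.1462G>A	p.Gly488Arg	missense	0.00015	0.00052	0	0	0.00120	0	0.00004	0
DUOX2	c.1060C>T	p.Arg354Trp	missense	0.00016	0.00008	0.00037	0	0.00005	0	0.00012	0.00029
DUOX2	c.602dupG	p.Gln202ThrfsTer99	frameshift	0.00086	0.00032	0.00055	0	0	0.00012	0.00158	0.00070
TSHR	c.202C>T	p.Pro68Ser	missense	0.00049	0.00004	0.00068	0.00174	0	0	0.00043	0.00115
TSHR	c.484C>G	p.Pro162Ala	missense	0.00014	0.00004	0.00008	0	0.00010	0	0.00025	0
TSHR	c.1349G>A	p.Arg450His	missense	0.00021	0	0.00008	0	0.00241	0.00004	0.00003	0.00013
TSHR	c.1637G>A	p.Trp546Ter	nonsense	0.00011	0.00008	0	0	0	0	0.00022	0
SLC26A7	c.1893delT	p.Phe631LeufsTer8	frameshift	0.00045	0.00004	0.00003	0	0	0.00420	0.00010	0
TSHB	c.373delT	p.Cys125ValfsTer10	frameshift	0.00016	0.00004	0	0	0	0.00004	0.00032	0
TRHR	c.1016delA	p.Gln339ArgfsTer14	frameshift	0.00012	0.00004	0	0	0	0	0.00024	0
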