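gene	hgvs_p	rsid	risk_zygosity
GBA	p.H294Q	rs367968666	het
GBA	p.E365K	rs2230288	het
GBA	p.T408M	rs75548401	het
GBA	p.N409S	rs76763715	het
GBA	p.L483P	rs421016	het
LRRK2	p.M1646T	rs35303786	het
LRRK2	p.S1647T	rs11564148	hom
PINK1	p.A340T	rs3738136	het
PINK1	p.G411S	rs45478900	het
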