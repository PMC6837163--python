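symbol	inheritance	core_pd	panel_member
GBA	risk_only	true	true
LRRK2	AD	true	true
PARK7	AR	true	true
PINK1	AR	true	true
PRKN	AR	true	true
SNCA	AD	true	true
VPS13C	AR	true	true
VPS35	AD	true	true
ATP13A2	AR	true	true
DNAJC6	AR	true	true
FBXO7	AR	true	true
SLC6A3	AR	true	true
SYNJ1	AR	true	true
DNAJC13	candidate	true	true
CHCHD2	candidate	true	true
PLA2G6	AR	true	true
EIF4G1	candidate	true	true
ATXN2	AD	false	true
GCH1	AD	false	true
SPG11	AR	false	true
TMEM230	candidate	false	true
UCHL1	candidate	false	true
HTRA2	candidate	false	true
GIGYF2	candidate	false	true
RIC3	candidate	false	true
PTRHD1	candidate	false	true
PODXL	candidate	false	true
ABCA7	candidate	false	true
DCTN1	candidate	false	true
C19orf12	AR	false	true
CP	AR	false	true
PANEL032	candidate	false	true
PANEL033	candidate	false	true
PANEL034	candidate	false	true
PANEL035	candidate	false	true
PANEL036	candidate	false	true
PANEL037	candidate	false	true
PANEL038	candidate	false	true
PANEL039	candidate	false	true
PANEL040	candidate	false	true
PANEL041	candidate	false	true
PANEL042	candidate	false	true
PANEL043	candidate	false	true
PANEL044	candidate	false	true
PANEL045	candidate	false	true
PANEL046	candidate	false	true
PANEL047	candidate	false	true
PANEL048	candidate	false	true
PANEL049	candidate	false	true
PANEL050	candidate	false	true
PANEL051	candidate	false	true
PANEL052	candidate	false	true
PANEL053	candidate	false	true
PANEL054	candidate	false	true
PANEL055	candidate	false	true
PANEL056	candidate	false	true
PANEL057	candidate	false	true
PANEL058	candidate	false	true
PANEL059	candidate	false	true
PANEL060	candidate	false	true
PANEL061	candidate	false	true
PANEL062	candidate	false	true
PANEL063	candidate	false	true
PANEL064	candidate	false	true
PANEL065	candidate	false	true
PANEL066	candidate	false	true
PANEL067	candidate	false	true
PANEL068	candidate	false	true
PANEL069	candidate	false	true
PANEL070	candidate	false	true
PANEL071	candidate	false	true
PANEL072	candidate	false	true
PANEL073	candidate	false	true
PANEL074	candidate	false	true
PANEL075	candidate	false	true
PANEL076	candidate	false	true
PANEL077	candidate	false	true
PANEL078	candidate	false	true
PANEL079	candidate	false	true
PANEL080	candidate	false	true
PANEL081	candidate	false	true
PANEL082	candidate	false	true
PANEL083	candidate	false	true
PANEL084	candidate	false	true
PANEL085	candidate	false	true
PANEL086	candidate	false	true
PANEL087	candidate	false	true
PANEL088	candidate	false	true
PANEL089	candidate	false	true
PANEL090	candidate	false	true
PANEL091	candidate	false	true
PANEL092	candidate	false	true
PANEL093	candidate	false	true
PANEL094	candidate	false	true
PANEL095	candidate	false	true
PANEL096	candidate	false	true
PANEL097	candidate	false	true
PANEL098	candidate	false	true
PANEL099	candidate	false	true
PANEL100	candidate	false	true
PANEL101	candidate	false	true
PANEL102	candidate	false	true
PANEL103	candidate	false	true
PANEL104	candidate	false	true
PANEL105	candidate	false	true
PANEL106	candidate	false	true
PANEL107	candidate	false	true
PANEL108	candidate	false	true
PANEL109	candidate	false	true
PANEL110	candidate	false	true
PANEL111	candidate	false	true
PANEL112	candidate	false	true
PANEL113	candidate	false	true
PANEL114	candidate	false	true
PANEL115	candidate	false	true
PANEL116	candidate	false	true
PANEL117	candidate	false	true
PANEL118	candidate	false	true
PANEL119	candidate	false	true
PANEL120	candidate	false	true
PANEL121	candidate	false	true
PANEL122	candidate	false	true
PANEL123	candidate	false	true
PANEL124	candidate	false	true
PANEL125	candidate	false	true
PANEL126	candidate	false	true
PANEL127	candidate	false	true
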