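population	code	region	latitude	early_doy	late_doy	n_genetic	n_years
English River	ENG	Labrador	54.966667	188	257	27	23
Campbellton River	CMP	Newfoundland	49.268516	163	242	25	28
Western Arm Brook	WAB	Newfoundland	51.19	172	239	18	28
Conne River	CNR	Newfoundland	47.923333	146	210	30	28
Northeast Placentia River	NPR	Newfoundland	47.285	178	234	30	15
Sand Hill	SH	Labrador	53.559196	169	241	19	20
Terra Nova River	TNR	Newfoundland	48.545	167	246	29	27
Miramichi Southwest	MSW	Maritimes	46.881667	159	288	23	27
Upsalquitch	UPS	Maritimes	47.57175	180	276	28	22
Nashwaak	NSH	Maritimes	46.118333	159	283	44	24
Miramichi Upper Northwest	MUN	Maritimes	46.936667	169	286	24	23
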