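species	marker_name	min_concentration	unit	assay
Hamamelis virginiana	tannins	3.0	percent	UV
Matricaria recutita	apigenin 7-glucoside	0.25	percent	HPLC
Maytenus ilicifolia	epicatechin	2.8	mg_per_g	HPLC
Mikania glomerata	coumarin	0.1	percent	HPLC
Panax ginseng	ginsenoside Rg1	0.2	percent	HPLC
Passiflora incarnata	total flavonoids	1.5	percent	UV
Peumus boldus	total alkaloids	0.1	percent	HPLC
Valeriana officinalis	valerenic acid	0.05	percent	HPLC
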