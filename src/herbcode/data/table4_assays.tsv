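labelled_species	sample_no	molecular_id	tlc	concentration	unit
Hamamelis virginiana	01	Hamamelis spp.	present	3.59	percent
Hamamelis virginiana	02	Betula spp.	absent	0.57	percent
Hamamelis virginiana	07	Tilia spp.	absent	0.23	percent
Hamamelis virginiana	08	Solanum spp.	present	4.22	percent
Hamamelis virginiana	09	Unidentified	absent	0.61	percent
Hamamelis virginiana	12	Hamamelis spp.	present	4.04	percent
Hamamelis virginiana	17	Lantana spp.	present	4.43	percent
Hamamelis virginiana	22	Persicaria spp.	absent	0.84	percent
Hamamelis virginiana	23	Sterculia urens	absent	0.20	percent
Hamamelis virginiana	28	Hamamelis spp.	present	4.13	percent
Matricaria recutita	05	Matricaria spp.	present	0.005	percent
Matricaria recutita	20	Matricaria spp.	present	0.001	percent
Matricaria recutita	24	Matricaria spp.	present	0.001	percent
Matricaria recutita	27	Matricaria recutita	present	0.002	percent
Maytenus ilicifolia	06	Roupala spp.	present	26.32	mg_per_g
Maytenus ilicifolia	10	Maytenus spp.	present	79.80	mg_per_g
Maytenus ilicifolia	22	Sorocea affinis	absent		mg_per_g
Maytenus ilicifolia	24	Fabaceae	absent		mg_per_g
Maytenus ilicifolia	28	Maytenus spp.	present	107.44	mg_per_g
Mikania glomerata	04	Mikania spp.	present	0.038	percent
Mikania glomerata	15	Mikania spp.	present	0.020	percent
Mikania glomerata	26	Mikania spp.	present	0.011	percent
Panax ginseng	05	Pfaffia dunaliana	absent		percent
Panax ginseng	08	Pfaffia dunaliana	absent		percent
Panax ginseng	10	Amaranthaceae	absent		percent
Panax ginseng	13	Pfaffia dunaliana	absent		percent
Panax ginseng	25	Pfaffia dunaliana	absent		percent
Passiflora incarnata	01	Passiflora spp.	absent	0.126	percent
Passiflora incarnata	03	Passiflora spp.	present	1.614	percent
Passiflora incarnata	08	Passiflora spp.	present	1.58	percent
Passiflora incarnata	13	Passiflora spp.	present	0.833	percent
Passiflora incarnata	18	Senna alexandrina	absent	0.154	percent
Passiflora incarnata	21	Passiflora spp.	present	0.97	percent
Passiflora incarnata	29	Senna alexandrina	absent	0.229	percent
Peumus boldus	06	Vernonia colorata	absent		percent
Peumus boldus	08	Peumus boldus	present	0.33	percent
Peumus boldus	26	Peumus boldus	present	0.72	percent
Peumus boldus	31	Peumus boldus	present	0.29	percent
Valeriana officinalis	02	Ageratum conyzoides	absent		percent
Valeriana officinalis	04	No sequence	absent		percent
Valeriana officinalis	06	Valeriana spp.	absent		percent
Valeriana officinalis	09	Unidentified	absent		percent
Valeriana officinalis	22	Valeriana spp.	absent		percent
Valeriana officinalis	24	Valeriana spp.	present	0.037	percent
Valeriana officinalis	25	Asteraceae	present	0.023	percent
Valeriana officinalis	29	Cissampelos spp.	present	0.050	percent
Valeriana officinalis	32	Valeriana spp.	absent		percent
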