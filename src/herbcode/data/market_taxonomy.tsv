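taxon	rank	genus	family
Hamamelis virginiana	species	Hamamelis	Hamamelidaceae
Matricaria recutita	species	Matricaria	Asteraceae
Maytenus ilicifolia	species	Maytenus	Celastraceae
Mikania glomerata	species	Mikania	Asteraceae
Panax ginseng	species	Panax	Araliaceae
Passiflora incarnata	species	Passiflora	Passifloraceae
Peumus boldus	species	Peumus	Monimiaceae
Valeriana officinalis	species	Valeriana	Caprifoliaceae
Hamamelis	genus	Hamamelis	Hamamelidaceae
Matricaria	genus	Matricaria	Asteraceae
Maytenus	genus	Maytenus	Celastraceae
Mikania	genus	Mikania	Asteraceae
Passiflora	genus	Passiflora	Passifloraceae
Valeriana	genus	Valeriana	Caprifoliaceae
Betula	genus	Betula	Betulaceae
Tilia	genus	Tilia	Malvaceae
Solanum	genus	Solanum	Solanaceae
Lantana	genus	Lantana	Verbenaceae
Persicaria	genus	Persicaria	Polygonaceae
Sterculia urens	species	Sterculia	Malvaceae
Roupala	genus	Roupala	Proteaceae
Sorocea affinis	species	Sorocea	Moraceae
Pfaffia dunaliana	species	Pfaffia	Amaranthaceae
Senna alexandrina	species	Senna	Fabaceae
Vernonia colorata	species	Vernonia	Asteraceae
Ageratum conyzoides	species	Ageratum	Asteraceae
Cissampelos	genus	Cissampelos	Menispermaceae
Fabaceae	family		Fabaceae
Amaranthaceae	family		Amaranthaceae
Asteraceae	family		Asteraceae
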