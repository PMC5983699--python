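species	rps16	rpl22	ycf15	ycf4	psaI	ycf1	rpl23	rps18	ndhB
Wisteria_floribunda	-	-	+	+	+	-	+	+	+
Wisteria_sinensis	-	-	+	+	+	-	+	+	-
Glycyrrhiza_glabra	-	-	-	+	+	+	+	+	+
Glycyrrhiza_lepidota	-	-	-	+	+	+	+	+	+
Astragalus_mongholicus	-	-	-	+	+	+	+	+	+
Astragalus_mongholicus_var_nakaianus	-	-	-	+	+	+	+	+	+
Caragana_kozlowii	-	-	-	+	+	+	+	+	+
Caragana_korshinskii	-	-	-	+	+	+	+	+	+
Caragana_microphylla	-	-	-	+	+	+	+	+	+
Caragana_rosea_var_rosea	-	-	-	+	+	+	+	+	+
Cicer_arietinum	-	-	-	-	+	+	+	+	+
Medicago_truncatula	-	-	-	-	+	+	+	+	+
Medicago_papillosa	-	-	-	-	+	+	+	+	+
Medicago_hybrida	-	-	-	-	+	+	+	+	+
Medicago_falcata	-	-	-	+	+	-	+	+	-
Trifolium_boissieri	-	-	-	-	+	+	+	+	+
Trifolium_glanduliferum	-	-	-	-	+	+	+	+	+
Trifolium_strictum	-	-	-	-	+	+	+	+	+
Lathyrus_sativus	-	-	-	+	-	+	-	+	+
Lathyrus_odoratus	-	-	-	-	-	+	+	-	+
Lathyrus_inconspicuus	-	-	-	-	-	+	+	+	+
Lathyrus_ochroleucus	-	-	-	-	+	+	+	+	+
Lathyrus_venosus	-	-	-	-	+	+	+	+	+
Lathyrus_palustris	-	-	-	-	+	+	+	+	+
Lathyrus_tingitanus	-	-	-	-	+	+	+	-	+
Lathyrus_davidii	-	-	-	-	-	+	+	+	+
Lathyrus_graminifolius	-	-	-	-	+	+	+	+	+
Lathyrus_littoralis	-	-	-	-	+	+	+	+	+
Lathyrus_japonicus	-	-	-	-	+	+	+	+	+
Lathyrus_pubescens	-	-	-	-	-	+	+	+	+
Lathyrus_clymenum	-	-	-	-	+	+	+	+	+
Pisum_sativum	-	-	-	-	+	+	-	+	+
Vicia_sativa	-	-	-	-	+	+	-	+	+
Lens_culinaris	-	-	-	-	+	-	+	-	+
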