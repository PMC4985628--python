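body_location	body_site	n_communities	n_nsd
airways	Anterior nares	259	256
gut	Stool	318	318
oral	Attached Keratinized gingiva	312	311
oral	Buccal mucosa	309	291
oral	Hard palate	301	288
oral	Palatine Tonsils	311	300
oral	Saliva	289	274
oral	Subgingival plaque	307	305
oral	Supragingival plaque	313	309
oral	Throat	304	291
oral	Tongue dorsum	315	311
skin	Left Antecubital fossa	147	147
skin	Left Retroauricular crease	271	270
skin	Right Antecubital fossa	154	152
skin	Right Retroauricular crease	283	280
urogenital	Mid vagina	133	133
urogenital	Posterior fornix	133	132
urogenital	Vaginal introitus	123	123
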