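body_location	body_site	n_communities	n_nsd
airways	Anterior nares	158	156
gut	Stool	186	185
oral	Attached Keratinized gingiva	180	179
oral	Buccal mucosa	181	180
oral	Hard palate	176	173
oral	Palatine Tonsils	184	182
oral	Saliva	159	158
oral	Subgingival plaque	183	183
oral	Supragingival plaque	188	187
oral	Throat	170	170
oral	Tongue dorsum	190	188
skin	Left Antecubital fossa	138	134
skin	Left Retroauricular crease	183	172
skin	Right Antecubital fossa	134	133
skin	Right Retroauricular crease	185	178
urogenital	Mid vagina	88	88
urogenital	Posterior fornix	86	86
urogenital	Vaginal introitus	86	86
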