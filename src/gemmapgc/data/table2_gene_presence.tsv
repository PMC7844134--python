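genome_id	hemF	hemN	hemJ	hemG	acsF	bchE	BphP	BphO	CuZnSOD	MnSOD
G_phototrophica_AP64	+	+	+	+	+	+	−	−	−	+
G_groenlandica_TET16	+	−	+	+	+	−	+	+	+	+
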