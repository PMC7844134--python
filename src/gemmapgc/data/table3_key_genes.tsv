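genome_id	puf	puh	bch	acsF	bchE	hemF	hemN	hemJ	hemG	BphP	BphO	RubisCO	Rho-like
ES-bin-14	+	+	+	+	−	+	−	−	−	−	−	−	−
ES-bin-29	−	+	−	−	−	−	−	−	−	−	−	+	−
ES-bin-51	+	+	+	+	−	+	−	−	−	+	+	−	−
ES-bin-78	−	−	−	−	−	−	−	−	−	−	−	−	−
LF-bin-215	−	−	−	−	−	−	−	−	−	−	−	−	+
LF-bin-339	+	+	+	+	−	+	+	−	+	+	+	−	+
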