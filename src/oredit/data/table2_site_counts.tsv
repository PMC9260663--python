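organelle	sample	total
chloroplast	CD	267
chloroplast	CDT	39
chloroplast	WD	18
chloroplast	WDT	21
mitochondria	CD	953
mitochondria	CDT	677
mitochondria	WD	594
mitochondria	WDT	767
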