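# Specifier species -> matrix OTU label overrides.
# Species absent below fall back to a genus-level match when that match
# is unique; ambiguous genera (two congeneric OTUs) need an entry here.
# The right-hand side must be reconciled against the OTU strings of the
# matrix actually analyzed; a missing right-hand side marks "no proxy".
species	otu
Pontosaurus lesinensis	Pontosaurus kornhuberi
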