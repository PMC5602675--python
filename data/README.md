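# External data drop-in

Place here (not redistributable, so not shipped):

- `supplementary_matrix.tnt` — the published supplementary TNT character
  matrix (xread format, all three basal 'dolichosaur' OTUs included).
- `tip_ages.tsv` — tab-separated `taxon<TAB>mean[<TAB>min<TAB>max]` fossil
  ages in Mya (means of the published tip priors).

With these present, `scripts/acceptance.py` and the data-gated acceptance
tests run end to end.
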