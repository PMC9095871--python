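# Published counts of ancestral syntenic associations per rodent
# ancestor and how many are connected by long-range interactions in
# mouse round spermatids.
lineage	associations_total	associations_connected
Muridae	10	7
Eumuroidea	13	7
Muroidea	25	15
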