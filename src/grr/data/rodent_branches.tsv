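# Published summary of chromosome rearrangements along the rodent
# lineage leading to mouse (mm10 reference): per-branch EBR counts,
# branch lengths (My), and rearrangement counts by type.  Branches are
# keyed by their child ancestor; the root branch has no event counts.
# total_depth_my: 73
branch	ebr_count	branch_time_my	inversions	fission_fusion	conserved_chr
Rodentia	4	10.0	NA	NA	NA
Mouse Clade + Ctenohystricia	10	2.0	13	12	15
Mouse Clade	30	1.1	12	13	14
Myodonta	41	14.9	22	32	9
Muroidea	75	10.0	22	21	13
Eumuroidea	13	12.3	16	30	6
Muridae	5	11.8	7	10	14
Mouse	54	20.9	19	11	13
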