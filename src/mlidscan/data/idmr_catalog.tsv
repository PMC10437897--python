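# Bundled hg19 iDMR catalog (1-based closed intervals).
# PPIEL and FAM50B intervals are exact published coordinates; the remaining
# intervals are representative hg19 loci from the imprinting literature and
# are intended for synthetic cohorts and examples, not clinical use.
# Full 77-region catalogs (Monk / Joshi) are user-supplied.
chrom	start	end	name	methylated_allele	excluded
chr1	39559298	39559744	PPIEL:Ex1-DMR	maternal	False
chr1	68516000	68517200	DIRAS3:Ex2-DMR	maternal	False
chr4	89618000	89619200	NAP1L5:TSS-DMR	maternal	False
chr5	135415693	135416613	VTRNA2-1:DMR	maternal	True
chr6	3849096	3849469	FAM50B:TSS-DMR	maternal	False
chr6	144328078	144329888	PLAGL1:alt-TSS-DMR	maternal	False
chr7	94285537	94287960	PEG10:TSS-DMR	maternal	False
chr11	2019295	2024123	H19/IGF2:IG-DMR	paternal	False
chr11	2720411	2722254	KCNQ1OT1:TSS-DMR	maternal	False
chr14	101290524	101293978	MEG3:TSS-DMR	paternal	False
chr15	99408496	99409650	IGF1R:Int2-DMR	maternal	False
chr21	40757510	40758276	WRB:alt-TSS-DMR	maternal	False
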