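# Curated restriction enzymes commonly used for 16S rRNA T-RFLP.
# Columns: name, recognition site (IUPAC), top-strand cut offset,
# bottom-strand cut offset (both counted from the 5' end of the site
# on the respective strand).  A full REBASE import is a documented
# extension point; this file covers the shipped defaults.
# name	site	cut_offset_top	cut_offset_bottom
CfoI	GCGC	3	1
HhaI	GCGC	3	1
HaeIII	GGCC	2	2
AluI	AGCT	2	2
MspI	CCGG	1	3
RsaI	GTAC	2	2
HinfI	GANTC	1	4
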