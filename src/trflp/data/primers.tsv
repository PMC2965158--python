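# Starter list of frequently used 16S rRNA gene primers.
# Convenience data only -- users may supply any custom primer.
# name	sequence	orientation
27F	AGAGTTTGATCMTGGCTCAG	forward
515F	GTGYCAGCMGCCGCGGTAA	forward
Arch21F	TTCCGGTTGATCCYGCCGGA	forward
519R	GWATTACCGCGGCKGCTG	reverse
907R	CCGTCAATTCMTTTRAGTTT	reverse
1492R	TACGGYTACCTTGTTACGACTT	reverse
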