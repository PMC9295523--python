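# Two-residue PPR code: amino acids at a motif's 5th and last positions ->
# preferred RNA nucleotide set. Entries are the canonical published
# combinations from experimentally characterized P/S motifs; any pair not
# listed here degrades to the full degenerate set [ACGU] at lookup time.
# Columns: aa_5th, aa_last, nucleotides (subset of ACGU, A<C<G<U order).
aa_5th	aa_last	nucleotides
T	D	G
T	N	A
S	N	A
S	D	G
N	D	U
N	N	CU
N	S	C
N	T	C
G	D	U
G	N	A
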