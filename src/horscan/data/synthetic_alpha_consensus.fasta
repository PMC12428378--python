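>synthetic_alpha_consensus 171 bp synthetic stand-in for a published alpha-satellite consensus monomer; AT-rich; user-overridable
ATGATGCCTGATGAATTTTTTGACTAAACTTACTATGTAACGGTCCGTTGGGGCTTAAAA
GTGCCTTGTCGCATGTACAAGTAATCTGAAAGGACCCACACTTACCCACGCCCTTGTACA
AAAACAAGGAGAGTAAATCTAATTGAGAGTTAACAGCCGGTACAAACGATA
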