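name	consensus	category
ABRE	ACGTG	hormone
AUXRR-core	GGTCCAT	hormone
ERE	ATTTCAAA	hormone
GARE	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TCA-element	CCATCTTTTT	hormone
TGACG-motif	TGACG	hormone
Box-W1	TTGACC	stress_defense
HSE	AAAAAATTTC	stress_defense
LTR	CCGAAA	stress_defense
MBS	CAACTG	stress_defense
TC-rich	ATTTTCTTCA	stress_defense
WUN-motif	AAATTTCCT	stress_defense
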