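repeat	orientation	family
GGTTCTGTAGATAGCGTCGAGGTCGGAAGCGGCA	forward	DR01
AATGTCCTAAGCAAGGATTTCTGGATTA	forward	DR02
GAAACGAGGACACTGACTATATGCCGGGCAAT	forward	DR03
AATATCAACTGCGTTGGTGGGGAGTACGTAGATACG	forward	DR04
CTTGAAGACTATATAGAGCAGAAGCCTTTAC	forward	DR05
AAGCACTTAGTACATGTAATACATAAGAGCATG	forward	DR06
AGATCCCGGCCACTCTCTGGCGAAGCTGA	forward	DR07
CCATAGTATATTTCCTAAGGGGATCATATGGGGCGT	forward	DR08
GAGCAGACGAACCGGATAGGTGCCTGCCCGTATGGAT	forward	DR09
AACAGGCGACTGGTCGTAGACGATTCATGTGAGTAC	forward	DR10
TATACCTCATGGCCCACACCGCATTCCGCGTTG	forward	DR11
GGAATACGTGCGATCAGACAAGTGGTCGA	forward	DR12
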