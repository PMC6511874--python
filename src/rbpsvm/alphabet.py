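"""The amino-acid alphabet and the tolerated ambiguity letters.

The feature space of the spectrum kernel is built over the 20 standard
amino acids only. Ambiguity / non-standard letters (B = Asx, J = Xle,
O = pyrrolysine, U = selenocysteine, X = unknown, Z = Glx) are tolerated in
input sequences but never enter the k-mer feature space: any window that
touches one is skipped at featurization.
"""

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "BJOUXZ"
VALID_LETTERS = frozenset(ALPHABET) | frozenset(AMBIGUOUS)
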