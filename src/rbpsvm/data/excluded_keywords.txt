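# Keywords whose carriers are removed from the negative set (nucleotide
# binders in the broad sense). Editable placeholder defaults; matching is
# case-insensitive.
RNA-binding
DNA-binding
Nucleotide-binding
ATP-binding
GTP-binding
Ribosomal protein
Ribonucleoprotein
Helicase
Aminoacyl-tRNA synthetase
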