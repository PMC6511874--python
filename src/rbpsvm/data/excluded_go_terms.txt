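# GO terms whose carriers are removed from the negative set.
# Editable placeholder defaults.
# nucleic acid binding
GO:0003676
# nucleotide binding
GO:0000166
# DNA binding
GO:0003677
# RNA binding
GO:0003723
# ATP binding
GO:0005524
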