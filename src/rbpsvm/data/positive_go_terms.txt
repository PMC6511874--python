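# GO terms defining the RNA-binding positive class: the root term
# "RNA binding" plus a small sub-term closure. Users should substitute the
# full closure exported from their ontology snapshot.
GO:0003723
# tRNA binding
GO:0000049
# snRNA binding
GO:0017069
# poly(A) RNA binding
GO:0008143
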