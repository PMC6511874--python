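# Pfam accessions of known / potential RNA-binding domains; proteins with a
# hit in any of these are removed from the negative set. Editable
# placeholder defaults (RRM, KH, S1, S4, zf-CCHC, PUF).
PF00076
PF00013
PF00575
PF01479
PF00098
PF00806
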