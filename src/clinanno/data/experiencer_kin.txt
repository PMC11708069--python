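# LIVB kin terms -> Family_member; plurals expanded at load.
madre
padre
hermano
hermana
hijo
hija
abuelo
abuela
familiar
progenitor
progenitora
cónyuge
tío
tía
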