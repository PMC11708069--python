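# LIVB terms that also convey age information -> Age attribute; plurals expanded at load.
adulto
adulta
adolescente
niño
niña
anciano
anciana
lactante
neonato
neonata
bebé
joven
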