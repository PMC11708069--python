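# Dosage forms, one per line, canonical singular; plurals expanded at load.
píldora
comprimido
cápsula
tableta
jarabe
solución
suspensión
crema
pomada
parche
inyección
supositorio
aerosol
gel
polvo
colirio
ampolla
vial
grageas
emulsión
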