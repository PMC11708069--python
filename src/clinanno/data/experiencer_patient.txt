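# LIVB terms denoting the patient (default experiencer); plurals expanded at load.
paciente
enfermo
enferma
sujeto
participante
voluntario
voluntaria
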