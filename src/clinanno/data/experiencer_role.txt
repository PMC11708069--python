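# LIVB personnel/role terms -> Other; plurals expanded at load.
investigador
investigadora
médico
médica
enfermero
enfermera
cirujano
cirujana
facultativo
facultativa
evaluador
evaluadora
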