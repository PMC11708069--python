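# Qualifier adjectives (severity, laterality, extent), canonical singular;
# plurals expanded at load.
grave
leve
severo
severa
moderado
moderada
agudo
aguda
crónico
crónica
bilateral
unilateral
izquierdo
izquierda
derecho
derecha
avanzado
avanzada
metastásico
metastásica
intenso
intensa
persistente
recurrente
refractario
refractaria
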