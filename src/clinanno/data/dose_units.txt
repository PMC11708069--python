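# Dose / concentration / strength units, one per line.  Matching is
# case-sensitive (mg vs MG).  Lines starting with "/" are the denominators
# accepted in compound units such as mg/kg or mg/m2.
mg
g
kg
mcg
µg
μg
ug
ng
ml
mL
l
L
dl
dL
UI
U
mEq
mmol
mol
%
gotas
unidades
/kg
/m2
/m²
/día
/dia
/h
/hora
/dosis
/ml
/mL
/l
/L
/toma
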