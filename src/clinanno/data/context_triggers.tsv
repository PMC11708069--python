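# ConText-style attribute triggers: pattern <TAB> attribute <TAB> direction
antecedentes de	History_of	pre
antecedente de	History_of	pre
historia de	History_of	pre
historial de	History_of	pre
antecedentes personales de	History_of	pre
antecedentes familiares de	Family_History_of	pre
historia familiar de	Family_History_of	pre
en caso de	Hypothetical	pre
si	Hypothetical	pre
se prevé	Future	pre
está previsto	Future	pre
está prevista	Future	pre
pendiente de	Future	pre
contraindicación a	Contraindicated	pre
contraindicación para	Contraindicated	pre
contraindicado	Contraindicated	pre
contraindicada	Contraindicated	pre
contraindicados	Contraindicated	pre
contraindicadas	Contraindicated	pre
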