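# Negation/speculation trigger table: pattern <TAB> polarity <TAB> direction <TAB> kind
# polarity: negation | speculation | any (termination terms end both scopes)
# direction: pre (scope runs forward from the cue) | post (backward)
# kind: cue | pseudo | termination
no	negation	pre	cue
sin	negation	pre	cue
ausencia de	negation	pre	cue
niega	negation	pre	cue
niegan	negation	pre	cue
descartar	negation	pre	cue
se descartó	negation	pre	cue
exclusión de	negation	pre	cue
ningún	negation	pre	cue
ninguna	negation	pre	cue
ninguno	negation	pre	cue
nunca	negation	pre	cue
tampoco	negation	pre	cue
negativo para	negation	pre	cue
descartado	negation	post	cue
descartada	negation	post	cue
negativo	negation	post	cue
negativa	negation	post	cue
ausente	negation	post	cue
ausentes	negation	post	cue
posible	speculation	pre	cue
posibles	speculation	pre	cue
probable	speculation	pre	cue
probables	speculation	pre	cue
probablemente	speculation	pre	cue
posiblemente	speculation	pre	cue
sospecha de	speculation	pre	cue
podría	speculation	pre	cue
podrían	speculation	pre	cue
quizá	speculation	pre	cue
quizás	speculation	pre	cue
aparentemente	speculation	pre	cue
sugestivo de	speculation	pre	cue
sugestiva de	speculation	pre	cue
compatible con	speculation	pre	cue
dudoso	speculation	pre	cue
dudosa	speculation	pre	cue
riesgo de	speculation	pre	cue
no solo	negation	pre	pseudo
no sólo	negation	pre	pseudo
sin dificultad	negation	pre	pseudo
sin cambios	negation	pre	pseudo
no obstante	negation	pre	pseudo
sin embargo	negation	pre	pseudo
pero	any	pre	termination
aunque	any	pre	termination
excepto	any	pre	termination
salvo	any	pre	termination
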