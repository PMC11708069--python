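# Administration routes, one per line.  Canonical lowercase forms;
# gender/number inflections are expanded at load.  Lines with a second
# tab-separated column "abbrev" are matched case-sensitively and unfolded.
oral
intravenoso
endovenoso
intramuscular
subcutáneo
cutáneo
tópico
inhalado
inhalatorio
sublingual
rectal
ocular
nasal
oftálmico
transdérmico
parenteral
epidural
intratecal
intraarticular
vaginal
IV	abbrev
IM	abbrev
SC	abbrev
VO	abbrev
SL	abbrev
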