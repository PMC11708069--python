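# Temporal entity rules: regex pattern <TAB> class <TAB> priority.
# {NUM}, {DIGITS}, {TUNIT}, {MONTH} are expanded by the loader; patterns are
# matched case-insensitively inside sentences, bounded by non-word context.
{NUM}\s+años	Age	50
cada\s+{NUM}\s+{TUNIT}	Frequency	30
{NUM}\s+(?:vez|veces)\s+(?:al|por)\s+(?:día|dia|semana|mes|año|hora|noche)	Frequency	30
(?:diariamente|semanalmente|mensualmente|anualmente|quincenalmente|trimestralmente)	Frequency	30
a\s+diario	Frequency	30
{NUM}\s+{TUNIT}	Duration	20
por\s+la\s+(?:mañana|tarde|noche)	Time	16
esta\s+(?:mañana|noche)	Time	16
(?:noche|madrugada|mediodía|mediodia|nocturno|nocturna)	Time	15
(?:pre|post|pos)-?(?:noche|madrugada|mediodía|mediodia)	Time	13
(?:pre|post|pos)-?(?:operatorio|operatoria|operatorios|operatorias|quirúrgico|quirúrgica|tratamiento|intervención|intervencion|parto|natal|trasplante|vacunación|vacunacion|infusión|infusion|menopáusico|menopausico|menopáusica|menopausica)	Date	12
(?:19|20)\d{2}	Date	10
{DIGITS}\s+de\s+{MONTH}(?:\s+de\s+(?:19|20)\d{2})?	Date	11
{MONTH}\s+de\s+(?:19|20)\d{2}	Date	11
(?:hoy|actualmente|ayer)	Date	10
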