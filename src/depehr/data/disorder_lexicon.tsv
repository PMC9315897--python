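# Representative bilingual depressive-disorder term lexicon (synthetic
# stand-in for a full SNOMED CT concept vocabulary under
# "trastorno depresivo", SCTID 35489007). User-overridable.
surface	language	category	concept_id	canonical
trastorno depresivo	es	disorder_term	35489007	trastorno depresivo
trastorn depressiu	ca	disorder_term	35489007	trastorno depresivo
depresión	es	disorder_term	35489007	trastorno depresivo
depressió	ca	disorder_term	35489007	trastorno depresivo
depresión mayor	es	disorder_term	370143000	depresión mayor
depressió major	ca	disorder_term	370143000	depresión mayor
episodio depresivo	es	disorder_term	871840004	episodio depresivo
episodi depressiu	ca	disorder_term	871840004	episodio depresivo
síndrome depresivo	es	disorder_term	191659001	síndrome depresivo
síndrome depressiva	ca	disorder_term	191659001	síndrome depresivo
distimia	both	disorder_term	78667006	distimia
trastorno distímico	es	disorder_term	78667006	distimia
trastorn distímic	ca	disorder_term	78667006	distimia
depresión reactiva	es	disorder_term	79298009	depresión reactiva
depressió reactiva	ca	disorder_term	79298009	depresión reactiva
depresión endógena	es	disorder_term	77486005	depresión endógena
depressió endògena	ca	disorder_term	77486005	depresión endógena
clínica depresiva	es	disorder_term	191659001	síndrome depresivo
clínica depressiva	ca	disorder_term	191659001	síndrome depresivo
sintomatología depresiva	es	disorder_term	394924000	sintomatología depresiva
simptomatologia depressiva	ca	disorder_term	394924000	sintomatología depresiva
ánimo deprimido	es	disorder_term	366979004	ánimo deprimido
ànim deprimit	ca	disorder_term	366979004	ánimo deprimido
humor depresivo	es	disorder_term	272022009	humor depresivo
humor depressiu	ca	disorder_term	272022009	humor depresivo
depresión posparto	es	disorder_term	58703003	depresión posparto
depressió postpart	ca	disorder_term	58703003	depresión posparto
depresión ansiosa	es	disorder_term	231504006	depresión ansiosa
depressió ansiosa	ca	disorder_term	231504006	depresión ansiosa
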