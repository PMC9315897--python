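# Default ICD-9-CM depressive-disorder code set (prefix semantics:
# a 3-digit or 4-digit code covers all of its subcodes). Overridable.
296.2   # major depressive disorder, single episode
296.3   # major depressive disorder, recurrent episode
298.0   # depressive type psychosis
300.4   # dysthymic disorder
309.0   # adjustment disorder with depressed mood
309.1   # prolonged depressive reaction
311     # depressive disorder, not elsewhere classified
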