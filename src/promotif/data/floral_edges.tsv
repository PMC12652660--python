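# Arabidopsis floral regulatory network: reported activation relationships
# among MADS-box organ-identity genes and flowering-time regulators.
# Columns: regulator <TAB> target <TAB> provenance (curated | putative)
PI	PI	curated
SEP3	SEP3	curated
PI	AP3	curated
AP3	PI	curated
SEP3	SEP1	curated
SEP3	SEP2	curated
SEP3	SEP4	curated
SEP3	AG	curated
SEP1	SEP3	curated
SEP2	SEP3	curated
SEP4	SEP3	curated
AG	SEP3	curated
LFY	AP1	curated
LFY	AG	curated
LFY	SOC1	curated
LFY	AGL24	putative
LFY	SVP	putative
LFY	FUL	putative
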