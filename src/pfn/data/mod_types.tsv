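ptm_type	residue	mod_id
phosphorylation	Ser	MOD:00046
phosphorylation	Thr	MOD:00047
phosphorylation	Tyr	MOD:00048
phosphorylation	*	MOD:00696
acetylation	Lys	MOD:00064
acetylation	*	MOD:00394
methylation	*	MOD:00599
ubiquitination	Lys	MOD:01148
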