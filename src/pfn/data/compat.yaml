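# PSI-MOD id -> residues chemically amenable to that modification
# (three-letter codes). Used by site projection to decide whether an
# aligned residue could carry the reference site's modification.
MOD:00046: [Ser, Thr, Tyr]
MOD:00047: [Ser, Thr, Tyr]
MOD:00048: [Ser, Thr, Tyr]
MOD:00696: [Ser, Thr, Tyr]
MOD:00064: [Lys]
MOD:00394: [Lys, Ser, Thr, Ala, Gly, Met]
MOD:00599: [Lys, Arg]
MOD:01148: [Lys]
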