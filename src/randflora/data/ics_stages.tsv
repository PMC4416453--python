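stage	older_ma	younger_ma
Burdigalian	20.44	15.97
Langhian	15.97	13.82
Serravallian	13.82	11.63
Tortonian	11.63	7.246
Messinian	7.246	5.333
Pliocene	5.333	2.58
Pleistocene	2.58	0.0117
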