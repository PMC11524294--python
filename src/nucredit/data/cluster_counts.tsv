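cluster	n_edited_genes	n_ppr
1	51	4
2	75	4
3	115	5
4	151	15
5	66	8
6	88	10
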