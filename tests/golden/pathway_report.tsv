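pathway_id	name	n_genes	n_targeted	proportion	n_validated
PW1	synthetic pathway 1	2	1	0.5	1
PW2	synthetic pathway 2	2	0	0	0
PW3	synthetic pathway 3	2	0	0	0
PW4	synthetic pathway 4	2	0	0	0
PW5	synthetic pathway 5	2	0	0	0
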