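species	cs_individuals	cs_sites	edna_reads	edna_sites
Crangonyx subterraneus	10	5	0	0
Niphargus auerbachi	30	7	23	1
Niphargus fontanus	79	5	412	2
Niphargus puteanus	91	2	254	1
Niphargus thienemanni	2	1	284	1
Niphargus tonywhitteni	42	7	76	3
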