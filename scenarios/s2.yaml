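# Scenario S2: a larger world for timing and stability checks.
seed: 1
n_contigs: 4
contig_length_bp: 2800000
n_genes: 800
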