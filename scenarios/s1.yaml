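# Scenario S1: the default small synthetic world (seconds to simulate).
seed: 1
n_contigs: 2
contig_length_bp: 1400000
n_genes: 200
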