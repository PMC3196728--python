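key	value
n_protein_genes	1557
n_transposase_genes	354
n_assigned_transposase_genes	329
n_full_no_dr	101
genome_bp	1880000
is_bp	183000
southern_interval_days	984
host_generation_hours	19
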