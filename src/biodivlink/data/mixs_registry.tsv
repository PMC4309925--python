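tag	requirement	attachment	mapped_term_label
target_gene	mandatory	pcr	target gene
target_subfragment	mandatory	pcr	target subfragment
mid	mandatory	library_preparation	multiplex identifier sequence
pcr_primers	mandatory	pcr
pcr_cond	mandatory	pcr
nucl_acid_ext	optional	dna_extraction
nucl_acid_amp	optional	pcr
seq_meth	optional	sequencing
lib_const_meth	optional	library_preparation
seq_qual_check	optional	analysis
chimera_check	optional	analysis
investigation_type	optional	sample
samp_size	optional	sample
env_material	optional	sample
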