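label	definition	target_ontology
targeted gene survey	is an assay which aims to provide information about taxonomic information and community diversity by mean of sequencing specimen genomic regions used as marker of identity or diversity	OBI
multiplexing	a planned process which consists in running a set of samples as a pool in one single instrument run of a process while retaining the ability to associate individual results to each of the samples	OBI
library sequence deconvolution	is a data transformation which uses sequence alignment and ‘multiplex identifier sequence’ information to pull together all reads belonging to a given single sample following the sequencing of a multiplexed library which combining several samples in one sequencing event	OBI
PCR program	is a plan specification which is executed during a PCR by a thermal cycler instrument that will iterate through the changes in temperature and duration of each of the annealing, denaturation, elongation steps	OBI
multiplex identifier sequence	is a nucleic acid sequence which is used in a ligation step of library preparation process to allow pooling of samples while maintaining ability to identify individual source material	OBI
OTU matrix	OTU matrix is a data item, organized as a table, where organismal taxonomic units, computed by sequence analysis and genetic distance calculation, are counted in a set of biological or environmental samples. The table is used to appraise biodiversity of a population or community of living organism	PCO
target gene	is a data item about a coding genomic region which is the focus of a planned process such as an assay.	OBI
target subfragment	is a data item about a genomic region which is the focus of a planned process such as an assay.	OBI
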