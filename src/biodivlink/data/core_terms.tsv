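label	definition	target_ontology	status	iri	as_printed
targeted gene survey	is an assay which aims to provide information about taxonomic information and community diversity by mean of sequencing specimen genomic regions used as marker of identity or diversity	OBI	released	https://w3id.org/biodivlink/term/targeted-gene-survey	false
multiplexing	a planned process which consists in running a set of samples as a pool in one single instrument run of a process while retaining the ability to associate individual results to each of the samples	OBI	released	https://w3id.org/biodivlink/term/multiplexing	false
library sequence deconvolution	is a data transformation which uses sequence alignment and ‘multiplex identifier sequence’ information to pull together all reads belonging to a given single sample following the sequencing of a multiplexed library which combining several samples in one sequencing event	OBI	released	https://w3id.org/biodivlink/term/library-sequence-deconvolution	false
PCR program	is a plan specification which is executed during a PCR by a thermal cycler instrument that will iterate through the changes in temperature and duration of each of the annealing, denaturation, elongation steps	OBI	released	https://w3id.org/biodivlink/term/pcr-program	false
multiplex identifier sequence	is a nucleic acid sequence which is used in a ligation step of library preparation process to allow pooling of samples while maintaining ability to identify individual source material	OBI	released	https://w3id.org/biodivlink/term/multiplex-identifier-sequence	false
OTU matrix	OTU matrix is a data item, organized as a table, where organismal taxonomic units, computed by sequence analysis and genetic distance calculation, are counted in a set of biological or environmental samples. The table is used to appraise biodiversity of a population or community of living organism	PCO	requested	https://w3id.org/biodivlink/term/otu-matrix	false
target gene	is a data item about a coding genomic region which is the focus of a planned process such as an assay.	OBI	released	https://w3id.org/biodivlink/term/target-gene	false
target subfragment	is a data item about a genomic region which is the focus of a planned process such as an assay.	OBI	released	https://w3id.org/biodivlink/term/target-subfragment	false
biodiversity assessment objective	an objective specification to provide information that can be used to gauge the diversity of an organismal community in an environmental sample	supporting	supporting	https://w3id.org/biodivlink/term/biodiversity-assessment-objective	false
sequence analysis objective	an objective specification to produce sequence data	supporting	supporting	http://purl.obolibrary.org/obo/OBI_020008	true
DNA extract	a material entity consisting of DNA isolated from a specimen or environmental sample	supporting	supporting	https://w3id.org/biodivlink/term/dna-extract	false
forward pcr primer	an oligonucleotide primer annealing to the antisense strand that bounds the amplified region on its 5' side	supporting	supporting	https://w3id.org/biodivlink/term/forward-pcr-primer	false
reverse pcr primer	an oligonucleotide primer annealing to the sense strand that bounds the amplified region on its 3' side	supporting	supporting	https://w3id.org/biodivlink/term/reverse-pcr-primer	false
single fragment library	a material entity consisting of prepared DNA fragments from one source material, ready for loading on a sequencing instrument	supporting	supporting	https://w3id.org/biodivlink/term/single-fragment-library	false
sequence analysis data transformation	a data transformation that derives community-level information from sequence reads	supporting	supporting	https://w3id.org/biodivlink/term/sequence-analysis-data-transformation	false
data item	an information content entity that is intended to be a truthful statement about something	supporting	supporting	https://w3id.org/biodivlink/term/data-item	false
population quality	a quality inhering in a population or community of living organisms, typically its diversity	supporting	supporting	https://w3id.org/biodivlink/term/population-quality	false
DNA sequencing	a planned process that determines the sequence of nucleotides in a DNA sample	supporting	supporting	https://w3id.org/biodivlink/term/dna-sequencing	false
library preparation	a planned process that converts nucleic acid extracts into a library suitable for sequencing	supporting	supporting	https://w3id.org/biodivlink/term/library-preparation	false
polymerase chain reaction	a planned process that amplifies a targeted genomic region with a thermostable polymerase and a primer pair	supporting	supporting	https://w3id.org/biodivlink/term/polymerase-chain-reaction	false
nucleic acid extraction	a material separation process that isolates nucleic acids from a sample	supporting	supporting	https://w3id.org/biodivlink/term/nucleic-acid-extraction	false
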