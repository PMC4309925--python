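# biodivlink

Targeted gene survey metadata as OBI-patterned linked data.

## The problem

Environmental gene surveys (16S rRNA, ITS, COI amplicon studies) estimate the
diversity of a microbial or organismal community by sequencing a marker gene
region. Their metadata are usually reported twice over: once against the
Genomic Standards Consortium's MIxS checklist (which descriptors to report —
`target_gene`, `pcr_primers`, `mid`, ...) and once as an ISA-Tab archive,
whose assay tables encode the experimental workflow positionally: material
and data node columns (`Sample Name`, `Extract Name`, `Raw Data File`)
interleaved with `Protocol REF` columns that stand for processes, executed in
column order. Neither representation makes its semantics explicit, so
questions such as *"what assays can be used to study biodiversity?"* cannot
be asked across archives.

`biodivlink` makes those semantics explicit. It parses ISA-Tab survey
archives, reconstructs the workflow graph, checks MIxS descriptor
compliance, and converts the result into an RDF instance graph that follows
the Ontology for Biomedical Investigations (OBI) assay design pattern, with
community-level terms (the OTU matrix) aimed at the Population and Community
Ontology (PCO). The resulting graphs are interrogated with SPARQL competency
queries and checked structurally against the pattern's axioms. It is aimed
at metadata curators and ontology developers working on sequence-based
biodiversity studies.

## The model

The core is a small vocabulary (eight survey classes plus supporting terms
and relations) and an axiom set instantiating the OBI assay pattern — an
assay has a specified *Material* input, a specified *Data* output, and
achieves an objective:

```
'targeted gene survey'
  'achieves_planned_objective' some 'biodiversity assessment objective'
  'has_part' some 'library preparation'
  'has_part' some 'DNA sequencing'
  'has_part' some ('library sequence deconvolution'
     and 'precedes' some ('sequence analysis data transformation'
         and 'has_specified_output' some ('data item'
             and 'is_about' some 'population quality')))
'library preparation'
  'has_part' some 'polymerase chain reaction'
  'has_specified_input' some 'DNA extract'
  'has_specified_input' some 'multiplex identifier sequence'
  'precedes' some 'DNA sequencing'
  'has_specified_output' some 'single fragment library'
'polymerase chain reaction'
  'has_specified_input' some 'forward pcr primer'
  'has_specified_input' some 'reverse pcr primer'
  ('realizes' o 'concretizes') some 'PCR program'
```

Conversion instantiates this pattern per assay table: one survey individual,
process individuals per protocol application ordered by `precedes`, primers
and multiplex identifiers minted as *process inputs* (a primer is an input to
library preparation, not a property of a sample), and the property chain
witnessed by an explicit intermediate plan individual. The terminal analysis
output is a `data item` that `is_about` a `population quality` — the
community diversity the survey was run to estimate — and is typed
`OTU matrix` when its name matches a configurable pattern. Note the
deliberate disambiguation of "barcode": the ligated pooling tag is a
`multiplex identifier sequence`; the marker-gene technique itself is a
*targeted gene survey*.

## Worked example

Generate a synthetic three-sample 16S survey archive, validate it, convert
it, and query it:

```
$ biodivlink make-fixture --samples 3 --genes 1 --seed 7 -o gut_survey
wrote archive BDL-3x1ud-7 to gut_survey

$ biodivlink validate gut_survey
MIxS compliance report
======================
All mandatory descriptors present.
pcr_primers: 3 occurrence(s), e.g. 'FWD:GCTAAAGACAATTACATAAC;REV:ATACACGTCAGCACGAAACT' at process:polymerase chain reaction
pcr_cond: 3 occurrence(s), e.g. 'initial denaturation:94C_3min; annealing:55C_30s; elongation:72C_90s; 35 cycles' at process:polymerase chain reaction
target_gene: 3 occurrence(s), e.g. '16S rRNA' at process:polymerase chain reaction
target_subfragment: 3 occurrence(s), e.g. 'V5-V6' at process:polymerase chain reaction
mid: 3 occurrence(s), e.g. 'TGTTGGCC' at process:library preparation
seq_meth: 3 occurrence(s), e.g. '454 GS FLX Titanium' at process:DNA sequencing
archive is valid

$ biodivlink convert gut_survey -o gut_survey.ttl --strict
wrote 188 statements to gut_survey.ttl

$ biodivlink query gut_survey.ttl --name biodiversity-assays
assay
https://w3id.org/biodivlink/data/BDL-3x1ud-7/survey/survey-1
```

The validation report shows every mandatory MIxS descriptor with the
workflow location it was found at — e.g. the multiplex identifier `TGTTGGCC`
attached to library preparation, where the tag is ligated. The 188-statement
Turtle graph contains one `targeted gene survey` individual (the single
binding of competency query 1) linked to its biodiversity assessment
objective, three library preparations and PCRs (one per sample), and six
primer individuals; `biodivlink query gut_survey.ttl --name primers` lists
all six (survey, primer) pairs. The same operations are available as a
library (`biodivlink.convert_archive`, `biodivlink.query_primers`,
`biodivlink.verify_pattern`, ...).

`biodivlink emit-ontology -o survey.ttl` writes the vocabulary itself
(21 classes, 12 subclass axioms) as Turtle, RDF/XML or an OWL
functional-syntax subset.

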