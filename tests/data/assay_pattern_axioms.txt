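# Hand-transcribed assay-pattern axiom block, one existential restriction per
# line: subject | relation | some(filler). Printed relation/label spellings
# kept as published; the test maps them onto canonical labels itself.
targeted gene survey | achieves_objective | some(biodiversity assessment objective)
targeted gene survey | has part | some(library preparation)
targeted gene survey | has_part | some(DNA sequencing)
targeted gene survey | has_part | some(and(library sequence deconvolution, precedes some(and(sequence analysis data transformation, has_specified_output some(and(data item, is about some(population quality)))))))
library preparation | has part | some(polymerase chain reaction)
library preparation | has_specified_input | some(DNA extract)
library preparation | has_specified_input | some(multiplexing sequence identifier)
library preparation | precedes | some(DNA sequencing)
library preparation | has_specified_output | some(single fragment library)
polymerase chain reaction | has_specified_input | some(forward pcr primer)
polymerase chain reaction | has_specified_input | some(reverse pcr primer)
polymerase chain reaction | realizes o concretizes | some(PCR program)
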