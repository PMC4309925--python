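# Competency query 1: What assays can be used to study biodiversity?
PREFIX rel: <https://w3id.org/biodivlink/relation/>
PREFIX term: <https://w3id.org/biodivlink/term/>

SELECT DISTINCT ?assay
WHERE {
  ?assay rel:achieves_planned_objective ?objective .
  ?objective a term:biodiversity-assessment-objective .
}
ORDER BY ?assay
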