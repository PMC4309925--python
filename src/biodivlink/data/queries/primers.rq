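# Competency query 2: Which PCR primers can be used to study biodiversity?
# Primers are specified inputs of processes that are (possibly nested) parts
# of a targeted gene survey, matching the class-level axioms.
PREFIX rel: <https://w3id.org/biodivlink/relation/>
PREFIX term: <https://w3id.org/biodivlink/term/>

SELECT DISTINCT ?survey ?primer
WHERE {
  ?survey a term:targeted-gene-survey ;
          rel:has_part+ ?process .
  ?process rel:has_specified_input ?primer .
  { ?primer a term:forward-pcr-primer } UNION { ?primer a term:reverse-pcr-primer }
}
ORDER BY ?survey ?primer
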