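# Methods

## Scope and model

`biodivlink` operationalizes a semantic model of targeted (amplicon-based)
gene surveys. A survey is modeled with the OBI assay design pattern: a
planned process with specified Material inputs and Data outputs that
achieves an objective. The survey's objective is deliberately the specific
*biodiversity assessment objective* rather than the generic sequence
production objective: the point of the assay is not the reads but an
information content entity (typically an OTU matrix) that is about a quality
of the sampled community — its diversity. The vocabulary therefore carries
eight survey-specific classes (targeted gene survey, multiplexing, library
sequence deconvolution, PCR program, multiplex identifier sequence, OTU
matrix, target gene, target subfragment; seven aimed at OBI, the OTU matrix
at PCO) plus the supporting classes and relations the axiom block needs.

Two modeling commitments run through everything:

- **Primers and multiplex identifiers are process inputs, never sample
  properties.** Attaching them to samples (as some archive schemas do)
  conflates sample identity with library identity; several libraries, one
  per targeted genomic region, are routinely derived from one sample.
- **"Barcode" is disambiguated.** The ligated pooling tag is a *multiplex
  identifier sequence* (an input to library preparation); the marker-gene
  technique itself is a *targeted gene survey*. The MIxS `mid` descriptor
  maps to the former, never to the survey.

## ISA-Tab interpretation

An assay table row encodes a left-to-right workflow chain whose first node
is a material and whose last node is a data file; `Protocol REF` columns
between nodes are processes, executed in column order. Choices where the
convention is silent:

- Qualifier columns (`Characteristics[...]`, `Parameter Value[...]`,
  `Comment[...]`, `Unit`, `Term Source REF`, `Term Accession Number`, and any
  unrecognized label) attach to the closest node or process column to their
  left.
- Node identity: nodes merge on (column label, name) within one table,
  never across tables — cross-table merging is what creates ambiguities
  about sample sizes and identity.
- Process identity: one process per row per `Protocol REF` column, except
  that applications identical in (column, protocol, parameters, output node)
  merge their inputs. This is exactly the multiplexing case: n library rows
  feeding one pooled sequencing output become one sequencing run with n
  inputs, while per-row PCR parameters keep PCRs distinct. The pre-merge
  multiplicity is preserved on each edge (`row_indices`), so the invariant
  "protocol applications = rows × protocol columns" remains checkable.
- The leftmost-material/rightmost-data contract is enforced for assay
  tables only; study tables legitimately end in `Sample Name`.
- Tables are read as bare UTF-8 TSV, cells verbatim, no quote handling, and
  ragged rows are hard errors with line numbers. Investigation files are
  parsed only for identifiers and study/assay file discovery.

## Conversion rules

Per assay table, one survey individual is minted; process individuals are
minted per (merged) workflow edge and typed via a protocol-label map
(user-overridable; unmapped labels are errors in strict mode, warnings plus
untyped individuals otherwise). Specific rules:

- `precedes` is emitted between consecutive processes of each row (the
  `follows` inverse is derivable and not materialized).
- The survey `has_part` every library preparation, sequencing,
  deconvolution, analysis and multiplexing process; each row's library
  preparation `has_part` that row's PCR.
- Library preparation takes the row's `DNA extract` and its multiplex
  identifier as specified inputs and outputs a minted `single fragment
  library` individual. The assay table has no library node column — its
  right neighbour is sequencing's data output — so typing that file as the
  library would conflate a material with a datum; minting is the faithful
  reading.
- The class-level property chain `realizes o concretizes some 'PCR program'`
  is witnessed by an explicit intermediate: PCR `realizes` a minted plan,
  which `concretizes` a `PCR program` individual. A shortcut predicate would
  not satisfy the chain.
- A `multiplexing` process is minted per pooled sequencing run, detected as
  a sequencing edge fed by two or more rows (a "pool" of one is structurally
  indistinguishable from an unpooled run).
- `pcr_primers` values of the form `FWD:<seq>;REV:<seq>` become two typed
  primer individuals keyed by sequence (shared primers across PCRs therefore
  deduplicate to one pair); free-text values yield one generic untyped
  primer individual plus a warning.
- The analysis output is typed `data item`, linked `is_about` to a minted
  `population quality`, and additionally typed `OTU matrix` when its name
  contains the configured pattern (default `"otu"`).
- Descriptor values are attached as plain literals in an artifact annotation
  namespace on the owning individual; full OBI value-specification modeling
  is out of scope.
- Every individual is a minted IRI — `<base>/<archive>/<kind>/<name>` with
  percent-encoded names, deterministic across runs, no blank nodes — so
  merged graphs from different archives never collide and round trips are
  set-equal.

IRIs for the vocabulary itself live in an artifact namespace with a sidecar
override table (`data/iri_overrides.tsv`) mapping labels to canonical OBO
PURLs where they exist; the atypical identifier `OBI_020008` recorded for
'sequence analysis objective' is preserved verbatim rather than "fixed", and
flagged `as_printed`. `achieves_objective` and the other spelling variants
(`has part`, `is about`, `multiplexing sequence identifier`) are registered
as aliases of the canonical labels.

## MIxS compliance

The bundled registry is a curated, editable subset: the survey-critical
descriptors (`target_gene`, `target_subfragment`, `mid`, `pcr_primers`,
`pcr_cond`) are mandatory by default, the rest (`nucl_acid_ext`,
`nucl_acid_amp`, `seq_meth`, and common optional fields) optional; strictness
is a data-file edit, not a code change. Matching is by normalized label
(lowercase; spaces/hyphens → underscores; idempotent), not column position —
positional matching is exactly what makes flat archive formats ambiguous.
Reported values are byte-identical to source cells, with the owning
node/process as attachment location.

## Pattern verification

`verify_pattern` is a closed-world structural check, not DL reasoning: for
every individual typed with an axiom subject class, each existential
restriction must be witnessed by explicit statements (recursively for nested
intersections, chain-aware for `realizes∘concretizes`). The mutation suite
inverts this: it collects, per (individual, restriction), the statements
common to all witness derivations, and verifies each single deletion is
detected. The competency queries are shipped as standard SPARQL text assets;
the primer query follows the axiom block — primers are specified inputs
reached via `has_part+` — rather than routing through the property chain,
which belongs to PCR programs, not primers.

## Synthetic fixtures and what they do (not) show

The generator emulates the *structure* of a gut-microflora-style 16S survey:
per-sample extraction, per-(sample, gene) PCR with primer pair and target
annotations, MID ligation at library preparation, sequencing pooled per gene
when multiplexed, deconvolution and analysis converging on one OTU matrix.
Defaults: three samples, one gene (16S rRNA, V5–V6), 20-mer primers and
8-mer MIDs as seeded random DNA strings drawn without replacement (each
sequence denotes one individual), 454-style method strings, seed 42. Every
row carries a MID — the tag is ligated whether or not runs are pooled; the
`multiplexed` flag controls only output pooling. Identical specs yield
byte-identical archives.

The fixtures contain no sequence data, no real sample names or primer
sequences, and no community composition; file names are placeholders.
Passing tests therefore demonstrate that the *mapping* is faithful and
complete for workflows of this shape — they say nothing about the
biological plausibility of any particular archive's content, and real
archives with exotic column dialects may need protocol-map or registry
configuration.

`expected_triples` is the independent oracle: closed-form counts per class
(e.g. library preparations = samples × genes always; sequencing runs =
genes when pooled; primer individuals = 2 × genes when shared, else
2 × samples × genes) and a per-predicate statement ledger summing to
`20 + 7n + 34R + 9S + 4M + 3P + I` (R = n·g rows, S sequencing runs, M
multiplexing processes, P primer individuals, I pooled-run input
statements). It is arithmetic over the spec, independent of the conversion
code, and the test grid (samples ∈ {1,3,10} × genes ∈ {1,2} × pooled ×
shared) requires exact equality.

## Numerical/structural edge cases

- Empty workflow → conversion error ("nothing to convert"); empty term/axiom
  sets still serialize to a valid ontology document.
- Empty cells break a row's chain locally: a process with no reachable
  input/output in its row emits no edge; validation reports, rather than
  throws, all contract violations (leftmost/rightmost, cycles,
  disconnected edges).
- Ontology round trips are compared on structural fingerprints (class,
  restriction, label and definition sets) because Turtle/RDF-XML use blank
  nodes for class expressions; instance graphs are blank-node-free and
  compared as statement sets.
- The OWL functional-syntax emitter covers the subset the vocabulary needs
  (declarations, annotations, subclass-of with nested
  someValuesFrom/intersections, property chains); its summarizer is a
  counting reader for round-trip checking, not a general parser.

## Problem sizes

Tests and the acceptance script run the full grid up to 10 samples × 2 genes
(20-row archives, ~1100-statement graphs); the whole suite completes in
seconds. Counts scale linearly, and nothing in the pipeline is
stochastic beyond the seeded fixture sequences.

## Known limitations

No DL reasoning over instances or the full OBI/PCO releases (the bundled
mini-module is self-contained); no ISA configuration-XML validation,
ISA-JSON, or SRA XML emission; no PROV/named-graph provenance; no
unit/regex validation of MIxS descriptor values; investigation metadata
beyond identifiers and file discovery is ignored.
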