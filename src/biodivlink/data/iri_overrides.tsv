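label	iri
sequence analysis objective	http://purl.obolibrary.org/obo/OBI_020008
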