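# Local stand-in for toxicology-alert membership (synthetic list, editable).
# One entry per line: 14-character InChIKey connectivity block, optional name after whitespace.
OQBAXQDDCDQSRW  aristolochic-acid-like alert structure
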