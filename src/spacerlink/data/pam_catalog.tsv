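# Default PAM catalog: IUPAC motif <TAB> side relative to the protospacer.
# Order matters: when several motifs match, the first in this file wins.
NGG	3prime
TTN	5prime
NNAGAAW	3prime
TTTV	5prime
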