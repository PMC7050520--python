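"""Tiny nucleotide-string helpers shared across modules."""

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def to_dna(s: str) -> str:
    """Uppercase and U->T so RNA-notation motifs match genomic sequence."""
    return s.upper().replace("U", "T")


def to_rna(s: str) -> str:
    return s.upper().replace("T", "U")
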