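"""Low-level DNA string helpers shared across the pipeline.

Genomes are handled as cDNA on the positive strand; 'U' is mapped to 'T'
at the I/O boundary so everything downstream works over {A,C,G,T,N}.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Strand-canonical form: the lexicographic min of a k-mer and its
    reverse complement (dsRNA libraries sequence both strands)."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def normalize(seq: str) -> str:
    """Uppercase and map RNA 'U' to 'T'."""
    return seq.upper().replace("U", "T")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
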