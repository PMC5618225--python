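"""Checks against deposited reference genomes.

The comparative results that are recomputable from public data are checked
here: genome lengths of the deposited sequences, the 5'/3'-extra lengths of
the newly deposited K2 isotype (extra5 = the anchor offset; extra3 = bases
past the classical CCTAGC 3' end), and the repeated 24-nt motif copy counts
in the 3' non-coding regions. Sequences are fetched from NCBI at call time
(network required) or supplied as local FASTA records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .annotate import annotate_genome, locate_anchor
from .compare import find_repeated_motif

# accession -> short name
REFERENCE_ACCESSIONS = {
    "MF957266": "M2-4",
    "U78817.1": "M1",
    "GU723494": "Mlus-4",
    "KT429819": "Mbarr-1",
    "AF515592.1": "Mzb",
}

M2_LEGACY_3P = "CCTAGC"


def fetch_genbank(
    accessions: list[str] | None = None, email: str = "mdsrna@example.org"
) -> dict[str, str]:
    """Fetch nucleotide FASTA records from NCBI (requires network)."""
    from io import StringIO

    from Bio import Entrez, SeqIO

    Entrez.email = email
    accs = accessions or list(REFERENCE_ACCESSIONS)
    out: dict[str, str] = {}
    with Entrez.efetch(
        db="nuccore", id=",".join(accs), rettype="fasta", retmode="text"
    ) as handle:
        text = handle.read()
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        for acc in accs:
            if rec.id.startswith(acc.split(".")[0]):
                out[acc] = str(rec.seq).upper().replace("U", "T")
    missing = set(accs) - set(out)
    if missing:
        raise RuntimeError(f"accessions not retrieved: {sorted(missing)}")
    return out


@dataclass
class ReferenceChecks:
    lengths: dict[str, int]
    m2_extra5: int | None
    m2_extra3: int | None
    motif_copies: dict[str, int]


def reference_checks(sequences: Mapping[str, str]) -> ReferenceChecks:
    """Recompute the deposited-sequence quantities from raw sequences keyed
    by accession (as fetched by fetch_genbank or loaded from FASTA)."""
    by_name = {REFERENCE_ACCESSIONS.get(acc, acc): seq for acc, seq in sequences.items()}
    lengths = {name: len(seq) for name, seq in by_name.items()}

    m2_extra5 = m2_extra3 = None
    if "M2-4" in by_name:
        seq = by_name["M2-4"]
        anchor = locate_anchor(seq)
        m2_extra5 = anchor if anchor is not None else None
        ann = annotate_genome(seq, "M2-4", legacy3_motif=M2_LEGACY_3P)
        if ann.legacy3_index is not None:
            m2_extra3 = len(seq) - (ann.legacy3_index + 1)

    motif_genomes = {
        name: by_name[name] for name in ("M1", "Mlus-4", "Mbarr-1", "Mzb") if name in by_name
    }
    regions = {}
    for name, seq in motif_genomes.items():
        ann = annotate_genome(seq, name)
        start = ann.orf.orf_end if ann.orf else len(seq) // 2
        regions[name] = (start, len(seq))
    copies: dict[str, int] = {}
    if len(motif_genomes) >= 2:
        families = find_repeated_motif(motif_genomes, k=24, max_mismatch=4, regions=regions)
        if families:
            best = max(families, key=lambda f: len(f.hits))
            copies = {name: best.copy_count(name) for name in motif_genomes}
    return ReferenceChecks(lengths, m2_extra5, m2_extra3, copies)
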