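"""Isotype and cross-virus comparison: pairwise alignment, core/extra
partitioning, variant catalogues with coding consequences, repeated-motif
discovery, and local identity scans.

Distinct isotypes of one virus type share a common core sequence and differ
in 5'/3'-terminal extras; locating the previously-known (shorter) sequence
inside a newly reconstructed genome partitions the new genome into
extra5 + core + extra3 and yields the catalogue of single-nucleotide
differences inside the core. Repeated-motif discovery finds short k-mer
families (the 24-nt element of the non-coding 3' region) shared across
genomes up to a Hamming-distance budget.

Alignment is affine-gap Needleman-Wunsch / Smith-Waterman as provided by
Biopython's PairwiseAligner, with match 1, mismatch -1, gap open -4 (first
gap base) and extend -1.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from ._dna import hamming


# --------------------------------------------------------------------------
# pairwise alignment


@dataclass
class AlignmentResult:
    score: float
    aligned_a: str  # gapped
    aligned_b: str
    identity: float  # matches / aligned columns, terminal gaps excluded
    a_start: int  # coordinates of the aligned span on each input
    a_end: int
    b_start: int
    b_end: int


def _make_aligner(
    mode: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -1.0,
    free_a_end_gaps: bool = False,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_a_end_gaps:
        # overhangs of sequence a beyond b cost nothing (semi-global)
        try:
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.query_end_gap_score = 0.0
    return aligner


def _gapped_strings(alignment) -> tuple[str, str]:
    return str(alignment[0]), str(alignment[1])


def _identity_core(ga: str, gb: str) -> tuple[float, int]:
    """Identity over aligned columns excluding terminal gap columns."""
    first = 0
    last = len(ga)
    while first < last and (ga[first] == "-" or gb[first] == "-"):
        first += 1
    while last > first and (ga[last - 1] == "-" or gb[last - 1] == "-"):
        last -= 1
    if last == first:
        return 0.0, 0
    matches = sum(ga[i] == gb[i] != "-" for i in range(first, last))
    return matches / (last - first), last - first


def _result(alignment, a: str, b: str) -> AlignmentResult:
    ga, gb = _gapped_strings(alignment)
    identity, _ = _identity_core(ga, gb)
    (a_blocks, b_blocks) = alignment.aligned
    if len(a_blocks):
        a_start, a_end = int(a_blocks[0][0]), int(a_blocks[-1][1])
        b_start, b_end = int(b_blocks[0][0]), int(b_blocks[-1][1])
    else:
        a_start = a_end = b_start = b_end = 0
    return AlignmentResult(
        float(alignment.score), ga, gb, identity, a_start, a_end, b_start, b_end
    )


def global_align(a: str, b: str, **scores) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch) alignment; deterministic: the first
    optimal traceback of the aligner's enumeration is reported."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner("global", **scores)
    return _result(next(iter(aligner.align(a, b))), a, b)


def local_align(a: str, b: str, **scores) -> AlignmentResult:
    """Best local (Smith-Waterman) alignment under the same scheme."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner("local", **scores)
    return _result(next(iter(aligner.align(a, b))), a, b)


# --------------------------------------------------------------------------
# variants


@dataclass
class Variant:
    ref_pos: int  # 1-based position on the reference
    ref: str
    alt: str
    kind: str  # SNV | ins | del
    consequence: str = ""  # e.g. "228T > I", "synonymous", "noncoding"

    @property
    def label(self) -> str:
        if self.kind == "SNV":
            return f"{self.ref_pos}{self.ref} > {self.alt}"
        if self.kind == "ins":
            return f"{self.ref_pos}ins{self.alt}"
        return f"{self.ref_pos}del{self.ref}"


_SNV_RE = re.compile(r"^(\d+)([ACGTN]) > ([ACGTN])$")
_INS_RE = re.compile(r"^(\d+)ins([ACGTN]+)$")
_DEL_RE = re.compile(r"^(\d+)del([ACGTN]+)$")


def parse_variant_label(label: str) -> Variant:
    """Inverse of Variant.label (round-trip identity)."""
    if m := _SNV_RE.match(label):
        return Variant(int(m.group(1)), m.group(2), m.group(3), "SNV")
    if m := _INS_RE.match(label):
        return Variant(int(m.group(1)), "", m.group(2), "ins")
    if m := _DEL_RE.match(label):
        return Variant(int(m.group(1)), m.group(2), "", "del")
    raise ValueError(f"cannot parse variant label {label!r}")


# --------------------------------------------------------------------------
# core/extra partition


@dataclass
class IsotypeComparison:
    reference_id: str
    query_id: str
    status: str  # ok | not_same_virus_type
    extra5: tuple[int, int]  # query coordinates, half-open
    core: tuple[int, int]
    extra3: tuple[int, int]
    core_identity: float
    variants: list[Variant] = field(default_factory=list)


def partition_core_extra(
    query: str,
    reference: str,
    query_id: str = "query",
    reference_id: str = "reference",
    min_core_identity: float = 0.8,
) -> IsotypeComparison:
    """Locate the previously-known reference inside the (longer) query.

    Semi-global alignment: query terminal overhangs are free, so unaligned
    query prefix/suffix become the 5'/3'-extra intervals and the aligned
    block is the common core. Variants (SNV/ins/del on the reference frame)
    are catalogued inside the core. Core identity below min_core_identity
    yields status 'not_same_virus_type' and no partition.
    """
    aligner = _make_aligner("global", free_a_end_gaps=True)
    alignment = next(iter(aligner.align(query, reference)))
    ga, gb = _gapped_strings(alignment)

    # strip columns where the reference row has terminal gaps
    first = 0
    last = len(gb)
    while first < last and gb[first] == "-":
        first += 1
    while last > first and gb[last - 1] == "-":
        last -= 1
    core_cols = range(first, last)
    matches = sum(ga[i] == gb[i] != "-" for i in core_cols)
    aligned_cols = last - first
    identity = matches / aligned_cols if aligned_cols else 0.0
    if identity < min_core_identity:
        return IsotypeComparison(
            reference_id, query_id, "not_same_virus_type",
            (0, 0), (0, 0), (0, 0), identity,
        )

    q_prefix = sum(1 for i in range(first) if ga[i] != "-")
    core_q_len = sum(1 for i in core_cols if ga[i] != "-")
    core_start = q_prefix
    core_end = q_prefix + core_q_len

    variants: list[Variant] = []
    qpos = q_prefix  # 0-based on query
    rpos = 0  # 0-based on reference
    for i in core_cols:
        qc, rc = ga[i], gb[i]
        if qc != "-" and rc != "-":
            if qc != rc:
                variants.append(Variant(rpos + 1, rc, qc, "SNV"))
            qpos += 1
            rpos += 1
        elif rc == "-":  # base present in query only: insertion after rpos
            variants.append(Variant(rpos, "", qc, "ins"))
            qpos += 1
        else:  # base present in reference only: deletion
            variants.append(Variant(rpos + 1, rc, "", "del"))
            rpos += 1
    return IsotypeComparison(
        reference_id,
        query_id,
        "ok",
        (0, core_start),
        (core_start, core_end),
        (core_end, len(query)),
        identity,
        variants,
    )


def call_coding_consequences(
    variants: Iterable[Variant],
    orf_start: int,
    orf_end: int,
    reference: str,
) -> list[Variant]:
    """Label each SNV inside the ORF with its codon-level consequence
    ("9V > M" style, or "synonymous"); everything else is "noncoding".

    orf_start/orf_end are 0-based half-open on the reference, stop codon
    included.
    """
    out = []
    for v in variants:
        pos0 = v.ref_pos - 1
        if v.kind != "SNV" or not (orf_start <= pos0 < orf_end - 3):
            v.consequence = "noncoding"
        else:
            ci = (pos0 - orf_start) // 3
            cs = orf_start + 3 * ci
            codon = reference[cs : cs + 3]
            mutated = list(codon)
            mutated[pos0 - cs] = v.alt
            aa_ref = str(Seq(codon).translate())
            aa_alt = str(Seq("".join(mutated)).translate())
            if aa_ref == aa_alt:
                v.consequence = "synonymous"
            else:
                v.consequence = f"{ci + 1}{aa_ref} > {aa_alt}"
        out.append(v)
    return out


# --------------------------------------------------------------------------
# repeated-motif discovery


@dataclass
class MotifHit:
    genome_id: str
    start: int
    end: int
    strand: str
    matches: int  # out of k
    label: str = ""  # A, B, C ... 5'->3' within a genome


@dataclass
class MotifFamily:
    consensus: str
    hits: list[MotifHit]

    def copy_count(self, genome_id: str) -> int:
        return sum(1 for h in self.hits if h.genome_id == genome_id)

    def genomes(self) -> set[str]:
        return {h.genome_id for h in self.hits}


def _block_bounds(k: int, n_blocks: int) -> list[tuple[int, int]]:
    size, rem = divmod(k, n_blocks)
    bounds = []
    pos = 0
    for i in range(n_blocks):
        step = size + (1 if i < rem else 0)
        bounds.append((pos, pos + step))
        pos += step
    return bounds


def find_repeated_motif(
    genomes: dict[str, str],
    k: int = 24,
    max_mismatch: int = 4,
    min_genomes: int = 2,
    regions: dict[str, tuple[int, int]] | None = None,
) -> list[MotifFamily]:
    """Cross-genome repeated k-mer families by greedy Hamming clustering.

    Every in-region k-mer is a candidate centroid, tried from most to least
    frequent (ties lexicographic). A family collects, per genome, maximal
    non-overlapping windows within max_mismatch of the centroid (left to
    right) and is kept when it spans at least min_genomes genomes. Hit
    windows are consumed, so later centroids cannot rediscover the same
    copies. Candidate windows are pre-screened with an exact-block index
    (pigeonhole over max_mismatch+1 blocks), which keeps the scan fast.
    """
    if min_genomes < 1 or max_mismatch < 0:
        raise ValueError("bad motif parameters")
    texts: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for gid, seq in genomes.items():
        s, e = (regions or {}).get(gid, (0, len(seq)))
        texts[gid] = seq[s:e]
        offsets[gid] = s

    n_blocks = max_mismatch + 1
    bounds = _block_bounds(k, n_blocks)
    block_index: dict[tuple[int, str], list[tuple[str, int]]] = {}
    counts: Counter[str] = Counter()
    for gid, text in texts.items():
        for p in range(len(text) - k + 1):
            win = text[p : p + k]
            counts[win] += 1
            for bi, (bs, be) in enumerate(bounds):
                block_index.setdefault((bi, win[bs:be]), []).append((gid, p))

    def build_hits(centroid: str, claimed: dict[str, set[int]]) -> list[MotifHit]:
        cand_pos: set[tuple[str, int]] = set()
        for bi, (bs, be) in enumerate(bounds):
            cand_pos.update(block_index.get((bi, centroid[bs:be]), ()))
        per_genome: dict[str, list[MotifHit]] = {}
        for gid, p in sorted(cand_pos):
            win = texts[gid][p : p + k]
            d = hamming(win, centroid)
            if d > max_mismatch:
                continue
            if any((p + off) in claimed[gid] for off in range(k)):
                continue
            per_genome.setdefault(gid, []).append(
                MotifHit(gid, offsets[gid] + p, offsets[gid] + p + k, "+", k - d)
            )
        # maximal non-overlapping hits, left to right, within each genome
        hits: list[MotifHit] = []
        for gid in sorted(per_genome):
            prev_end = -1
            kept: list[MotifHit] = []
            for h in sorted(per_genome[gid], key=lambda h: h.start):
                if h.start >= prev_end:
                    kept.append(h)
                    prev_end = h.end
            for i, h in enumerate(kept):
                h.label = chr(65 + i)
            hits.extend(kept)
        return hits

    # score every candidate centroid first, then accept best-first: the
    # centroid gathering the most copies wins over shifted/partial look-alikes
    no_claims: dict[str, set[int]] = {gid: set() for gid in texts}
    scored: list[tuple[tuple, str]] = []
    for centroid in counts:
        hits = build_hits(centroid, no_claims)
        if len({h.genome_id for h in hits}) < min_genomes:
            continue
        score = (-len(hits), -sum(h.matches for h in hits), centroid)
        scored.append((score, centroid))
    scored.sort()

    claimed: dict[str, set[int]] = {gid: set() for gid in texts}
    families: list[MotifFamily] = []
    for _, centroid in scored:
        hits = build_hits(centroid, claimed)
        if len({h.genome_id for h in hits}) < min_genomes:
            continue
        for h in hits:
            local = h.start - offsets[h.genome_id]
            claimed[h.genome_id].update(range(local, local + k))
        hits.sort(key=lambda h: (h.genome_id, h.start))
        families.append(MotifFamily(centroid, hits))
    return families


# --------------------------------------------------------------------------
# local identity scan


@dataclass
class LocalBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_length: int
    identity: float


def local_identity_scan(
    region_a: str, region_b: str, min_length: int = 20
) -> Optional[LocalBlock]:
    """Best Smith-Waterman block of aligned length >= min_length with its
    identity fraction; None when no such block exists."""
    if not region_a or not region_b:
        return None
    res = local_align(region_a, region_b)
    ga, gb = res.aligned_a, res.aligned_b
    identity, cols = _identity_core(ga, gb)
    if cols < min_length:
        return None
    return LocalBlock(
        res.a_start, res.a_end, res.b_start, res.b_end, cols, identity
    )
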