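"""Synthetic M-virus genome and read simulation.

M satellite dsRNAs (1.3-2.5 kb) share a stereotyped anatomy: a conserved
5'-GAAAAA motif taken as position 1, a preprotoxin ORF in the 5' half, a
central adenine-rich region, repeated short motifs and a 3'-terminal
stem-loop (TRE) in the non-coding 3' half, and - in many isotypes - "extra"
terminal sequences beyond the classically accepted 5' and 3' ends. The
generator plants each of these features at recorded coordinates so that
every downstream stage (QC, assembly, terminal extension, annotation,
comparative analyses) can be tested by parameter recovery.

Reads emulate a desk-scale paired/single-end short-read run over purified
dsRNA: both strands sampled evenly, i.i.d. substitution errors, two-level
phred qualities, optional trailing poly-N. Fragment starts are drawn over
an interval extending one read-length beyond the 5' terminus and clipped to
the molecule, so terminal fragments truncate at the physical ends of the
dsRNA - which is what keeps the termini covered and recoverable, as in real
libraries from a linear molecule.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from ._dna import revcomp
from .io import FastqRecord

ALPHABET = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in ALPHABET
    for b in ALPHABET
    for c in ALPHABET
    if a + b + c not in ("TAA", "TAG", "TGA")
]

ANCHOR = "GAAAAA"
_LEADER_LEN = 14  # nt between the anchor and the ORF start codon


class GenomeSizingError(ValueError):
    """Requested features do not fit in total_length."""


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic M-virus-like genome."""

    total_length: int = 1800
    extra5_length: int = 60
    extra3_length: int = 50
    orf_length_aa: int = 300
    polyA_runs: list[tuple[int, float]] = field(default_factory=lambda: [(32, 0.9)])
    motif_copies: int = 2
    motif_mismatches_per_copy: int = 0
    tre_stem_length: int = 10
    tre_loop_length: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (200 <= self.total_length <= 10_000):
            raise GenomeSizingError("total_length out of supported range")
        if self.extra5_length < 0 or self.extra3_length < 0:
            raise GenomeSizingError("extra lengths must be non-negative")
        if self.orf_length_aa < 20:
            raise GenomeSizingError("ORF must be at least 20 codons")
        if self.tre_loop_length < 3:
            raise GenomeSizingError("TRE loop must be >= 3 nt")
        if self.tre_stem_length < 4:
            raise GenomeSizingError("TRE stem must be >= 4 bp")
        for run_len, purity in self.polyA_runs:
            if run_len < 1 or not (0.5 <= purity <= 1.0):
                raise GenomeSizingError("poly(A) run length/purity out of range")


MOTIF_K = 24


@dataclass
class TruthTable:
    """Ground-truth coordinates for one generated genome.

    All intervals are 0-based half-open on the positive strand.
    """

    genome_id: str
    length: int
    anchor: int  # index of the G of GAAAAA
    orf: tuple[int, int]
    polyA: list[tuple[int, int]]
    motifs: list[tuple[int, int]]
    tre: tuple[int, int]
    extra5: tuple[int, int]
    extra3: tuple[int, int]
    motif_consensus: str
    kex2_aa_positions: list[int] = field(default_factory=list)
    nglyc_aa_positions: list[int] = field(default_factory=list)

    @property
    def legacy3_index(self) -> int:
        """0-based index of the last base of the legacy (pre-extra) 3' end."""
        return self.extra3[0] - 1

    def core_interval(self) -> tuple[int, int]:
        return (self.extra5[1], self.extra3[0])

    def rows(self) -> Iterator[tuple]:
        yield (self.genome_id, "anchor", self.anchor, self.anchor + 6, "+", "")
        yield (self.genome_id, "extra5", *self.extra5, "+", "")
        yield (self.genome_id, "orf", *self.orf, "+", "")
        for i, iv in enumerate(self.polyA):
            yield (self.genome_id, "polyA", *iv, "+", f"run={i}")
        for i, iv in enumerate(self.motifs):
            yield (self.genome_id, "motif", *iv, "+", f"copy={chr(65 + i)}")
        yield (self.genome_id, "tre", *self.tre, "+", "")
        yield (self.genome_id, "extra3", *self.extra3, "+", "")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["genome_id", "feature", "start", "end", "strand", "note"])
            for row in self.rows():
                w.writerow(row)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=n)) if n else ""


def _polya_segment(rng: np.random.Generator, length: int, purity: float) -> str:
    # impurities stay interior so the run starts and ends on A and the
    # planted interval is exactly recoverable
    seg = ["A"] * length
    n_impure = min(int((1.0 - purity) * length + 1e-9), max(0, length - 4))
    if n_impure:
        pos = rng.choice(length - 4, size=n_impure, replace=False) + 2
        for p in pos:
            seg[p] = str(rng.choice(["C", "G", "T"]))
    return "".join(seg)


def _orf_segment(
    rng: np.random.Generator, n_aa: int
) -> tuple[str, list[int], list[int]]:
    """ATG + random sense codons + stop, with planted Kex2 (KR) and
    N-glycosylation (N-X-S/T) motifs at recorded 1-based aa positions."""
    codons = ["ATG"] + [str(rng.choice(_SENSE_CODONS)) for _ in range(n_aa - 1)]
    kex2: list[int] = []
    nglyc: list[int] = []
    if n_aa >= 30:
        # Kex2 dibasic K-R with cleavage after R
        p = n_aa // 3
        codons[p - 1], codons[p] = "AAA", "AGA"  # K, R
        kex2.append(p + 1)  # position of R (1-based, cleavage after it)
        # N-X-S sequon, X != P
        q = (2 * n_aa) // 3
        codons[q - 1], codons[q], codons[q + 1] = "AAT", "GCT", "TCT"  # N, A, S
        nglyc.append(q)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))
    return "".join(codons) + stop, kex2, nglyc


def _tre_segment(rng: np.random.Generator, stem: int, loop: int) -> str:
    # GC-rich arm so the hairpin is thermodynamically favourable
    arm = "".join(rng.choice(list("GGCCAT"), size=stem))
    loop_seq = _random_seq(rng, loop)
    return arm + loop_seq + revcomp(arm)


def _scrub_anchor_lookalikes(seq: list[str], start: int, end: int) -> None:
    """Break any GAAAAA occurrence starting in [start, end)."""
    text = "".join(seq)
    i = text.find(ANCHOR, start)
    while i != -1 and i < end:
        seq[i] = "C"
        text = "".join(seq)
        i = text.find(ANCHOR, i + 1)


def generate_genome(spec: GenomeSpec, genome_id: str = "synth") -> tuple[str, TruthTable]:
    """Build one positive-strand genome plus its ground-truth table.

    Raises GenomeSizingError when the requested features cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    orf_nt = 3 * spec.orf_length_aa + 3
    tre_nt = 2 * spec.tre_stem_length + spec.tre_loop_length
    n_polya = len(spec.polyA_runs)
    polya_nt = sum(length for length, _ in spec.polyA_runs)

    # flexible spacers: after ORF, after each poly(A) run, after each motif
    # copy, and a 3' tail ending the legacy genome
    flex_mins = [8] + [6] * n_polya + [4] * spec.motif_copies + [6]
    fixed = (
        spec.extra5_length
        + len(ANCHOR)
        + _LEADER_LEN
        + orf_nt
        + polya_nt
        + MOTIF_K * spec.motif_copies
        + tre_nt
        + spec.extra3_length
    )
    slack = spec.total_length - fixed - sum(flex_mins)
    if slack < 0:
        raise GenomeSizingError(
            f"features need {fixed + sum(flex_mins)} nt but total_length is "
            f"{spec.total_length}"
        )
    # the 3' tail (last flex segment) stays minimal so the TRE hairpin sits
    # near the legacy 3' terminus, as it does in real genomes
    n_alloc = len(flex_mins) - 1
    extra_alloc = list(rng.multinomial(slack, np.ones(n_alloc) / n_alloc)) + [0]
    flex = [m + int(e) for m, e in zip(flex_mins, extra_alloc)]

    consensus = _random_seq(rng, MOTIF_K)
    orf_seq, kex2, nglyc = _orf_segment(rng, spec.orf_length_aa)

    parts: list[str] = []
    pos = 0

    def _emit(s: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(s)
        iv = (pos, pos + len(s))
        pos += len(s)
        return iv

    extra5_iv = _emit(_random_seq(rng, spec.extra5_length))
    anchor_iv = _emit(ANCHOR)
    _emit(_random_seq(rng, _LEADER_LEN))
    orf_iv = _emit(orf_seq)
    fi = iter(flex)
    _emit(_random_seq(rng, next(fi)))  # post-ORF spacer
    polya_ivs = []
    for run_len, purity in spec.polyA_runs:
        polya_ivs.append(_emit(_polya_segment(rng, run_len, purity)))
        _emit(_random_seq(rng, next(fi)))
    motif_ivs = []
    for _ in range(spec.motif_copies):
        copy = list(consensus)
        if spec.motif_mismatches_per_copy:
            mpos = rng.choice(MOTIF_K, size=spec.motif_mismatches_per_copy, replace=False)
            for p in mpos:
                copy[p] = str(rng.choice([b for b in ALPHABET if b != copy[p]]))
        motif_ivs.append(_emit("".join(copy)))
        _emit(_random_seq(rng, next(fi)))
    tre_iv = _emit(_tre_segment(rng, spec.tre_stem_length, spec.tre_loop_length))
    _emit(_random_seq(rng, next(fi)))  # legacy 3' tail
    extra3_iv = _emit(_random_seq(rng, spec.extra3_length))

    assert pos == spec.total_length, "segment accounting is off"
    seq = list("".join(parts))
    # no anchor look-alike may sit between the true anchor and the ORF start,
    # or the ORF-proximal anchor policy would pick the wrong G
    _scrub_anchor_lookalikes(seq, anchor_iv[0] + 1, orf_iv[0])
    # no ATG upstream of the planted start codon: an upstream in-frame ATG
    # with no intervening stop would genuinely lengthen the ORF and shift
    # the annotated start away from the planted one
    text = "".join(seq)
    p = text.find("ATG")
    while p != -1 and p <= orf_iv[0] - 3:
        seq[p + 1] = "C"
        text = "".join(seq)
        p = text.find("ATG", p + 1)
    # crisp poly(A) boundaries: the flanking spacer bases must not be A
    for s, e in polya_ivs:
        if s > 0 and seq[s - 1] == "A":
            seq[s - 1] = "C"
        if e < len(seq) and seq[e] == "A":
            seq[e] = "C"
    genome = "".join(seq)
    assert genome[anchor_iv[0] : anchor_iv[0] + 6] == ANCHOR

    truth = TruthTable(
        genome_id=genome_id,
        length=spec.total_length,
        anchor=anchor_iv[0],
        orf=orf_iv,
        polyA=polya_ivs,
        motifs=motif_ivs,
        tre=tre_iv,
        extra5=extra5_iv,
        extra3=extra3_iv,
        motif_consensus=consensus,
        kex2_aa_positions=kex2,
        nglyc_aa_positions=nglyc,
    )
    return genome, truth


@dataclass
class ReadSimParams:
    read_length: int = 100
    coverage: float = 100.0
    substitution_error_rate: float = 0.0
    quality_high: int = 37
    quality_low: int = 20
    fraction_low_quality_reads: float = 0.0
    polyN_tail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_error_rate <= 0.2):
            raise ValueError("substitution_error_rate must be in [0, 0.2]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for q in (self.quality_high, self.quality_low):
            if not (2 <= q <= 41):
                raise ValueError("quality values must be in [2, 41]")


def simulate_reads(genome: str, params: ReadSimParams) -> list[FastqRecord]:
    """Simulate both-strand reads with substitution errors.

    Expected read count is coverage * len(genome) / read_length (rounded).
    Fragment start positions range one read-length upstream of the 5' end
    and are clipped to the molecule, so reads at the termini are truncated
    rather than absent.
    """
    G = len(genome)
    rl = params.read_length
    if rl > G:
        raise ValueError(f"read_length {rl} exceeds genome length {G}")
    rng = np.random.default_rng(params.seed)
    n_reads = int(round(params.coverage * G / rl))

    starts_raw = rng.integers(-(rl - 1), G, size=n_reads)
    minus = rng.random(n_reads) < 0.5
    low_q = rng.random(n_reads) < params.fraction_low_quality_reads
    polyn = rng.random(n_reads) < params.polyN_tail_fraction

    base_idx = {b: i for i, b in enumerate(ALPHABET)}
    reads: list[FastqRecord] = []
    for i in range(n_reads):
        s = max(0, int(starts_raw[i]))
        e = min(G, int(starts_raw[i]) + rl)
        seq = genome[s:e]
        if minus[i]:
            seq = revcomp(seq)
        if params.substitution_error_rate > 0:
            arr = list(seq)
            errs = np.nonzero(rng.random(len(arr)) < params.substitution_error_rate)[0]
            for p in errs:
                shift = int(rng.integers(1, 4))
                arr[p] = ALPHABET[(base_idx[arr[p]] + shift) % 4]
            seq = "".join(arr)
        q = params.quality_low if low_q[i] else params.quality_high
        quals = [q] * len(seq)
        if polyn[i] and len(seq) >= 25:
            t = int(rng.integers(5, 16))
            seq = seq[:-t] + "N" * t
            quals[-t:] = [2] * t
        strand = "rev" if minus[i] else "fwd"
        reads.append(FastqRecord(f"read{i:06d}.{strand}", seq, quals))
    return reads


def simulate_paired_reads(
    genome: str, params: ReadSimParams, insert_mean: int = 300, insert_sd: int = 30
) -> tuple[list[FastqRecord], list[FastqRecord]]:
    """Paired-end variant: /1 and /2 reads from fragments of ~insert_mean nt.

    Pairing is cosmetic for this pipeline (the extension algorithm consumes
    reads individually); provided for format compatibility.
    """
    G = len(genome)
    rl = params.read_length
    rng = np.random.default_rng(params.seed)
    n_pairs = int(round(params.coverage * G / (2 * rl)))
    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    for i in range(n_pairs):
        ins = max(rl, int(rng.normal(insert_mean, insert_sd)))
        s = int(rng.integers(0, max(1, G - ins + 1)))
        frag = genome[s : s + ins]
        fwd = rng.random() < 0.5
        if not fwd:
            frag = revcomp(frag)
        q = [params.quality_high] * rl
        r1.append(FastqRecord(f"pair{i:06d}/1", frag[:rl], q[: len(frag[:rl])]))
        mate = revcomp(frag[-rl:])
        r2.append(FastqRecord(f"pair{i:06d}/2", mate, [params.quality_high] * len(mate)))
    return r1, r2
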