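"""Iterative terminal extension and map-back consensus.

The distinguishing reconstruction step for these genomes: de novo assembly
recovers the body of a 1.3-2.5 kb molecule but coverage pruning can clip
the physical termini, and the classically accepted ends (5'-GAAAAA, the
3'-TRE) may hide further "extra" sequence. Each round collects every read
whose overlap with the current contig end is 100% identical over at least
`min_overlap` bases and which overhangs past it; overhang columns are
stacked and the contig grows base by base while per-column support and
majority agreement hold. Both ends are extended each round; the process
repeats until a round adds nothing (or max_rounds).

Verification maps all reads back by exact seed + ungapped comparison,
reports per-base depth and majority, and exports a curated consensus.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import revcomp
from .config import PipelineConfig
from .io import FastqRecord

log = logging.getLogger(__name__)


@dataclass
class OverlapHit:
    read_id: str
    strand: str  # '+' read as given, '-' reverse complement
    overlap_length: int
    overhang: str  # bases the read contributes past the contig end

    def __post_init__(self) -> None:
        if not self.overhang:
            raise ValueError("an OverlapHit must have a non-empty overhang")


@dataclass
class ExtensionRound:
    index: int
    added5: str
    added3: str
    support5: list[int] = field(default_factory=list)
    support3: list[int] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)

    @property
    def bases_added(self) -> int:
        return len(self.added5) + len(self.added3)


class ReadIndex:
    """Exact-substring index over reads and their reverse complements.

    Maps every w-mer of every oriented read to (read position, offset,
    strand) so that a contig's terminal w-mer pulls out all candidate
    overlapping reads in one lookup.
    """

    def __init__(self, reads: Iterable[FastqRecord], w: int):
        self.w = w
        # canonical processing order: sort by id for determinism
        self.reads = sorted(reads, key=lambda r: r.id)
        self.index: dict[str, list[tuple[int, int, str]]] = {}
        for ri, read in enumerate(self.reads):
            for strand, seq in (("+", read.bases), ("-", revcomp(read.bases))):
                for off in range(len(seq) - w + 1):
                    key = seq[off : off + w]
                    if "N" in key:
                        continue
                    self.index.setdefault(key, []).append((ri, off, strand))

    def oriented(self, ri: int, strand: str) -> str:
        seq = self.reads[ri].bases
        return seq if strand == "+" else revcomp(seq)

    def overlaps_3prime(self, contig: str) -> list[OverlapHit]:
        """Reads whose 100%-identical overlap of >= w bases reaches the 3'
        contig end and which overhang past it (contained reads excluded)."""
        w = self.w
        if len(contig) < w:
            return []
        pattern = contig[-w:]
        hits: list[OverlapHit] = []
        for ri, off, strand in self.index.get(pattern, ()):
            seq = self.oriented(ri, strand)
            overlap = off + w
            start_on_contig = len(contig) - overlap
            if start_on_contig < 0:
                continue  # read would begin before the contig does
            if len(seq) <= overlap:
                continue  # fully contained, no overhang
            if seq[:overlap] != contig[start_on_contig:]:
                continue  # mismatch somewhere in the overlap: not 100%
            hits.append(
                OverlapHit(self.reads[ri].id, strand, overlap, seq[overlap:])
            )
        return hits

    def overlaps_5prime(self, contig: str) -> list[OverlapHit]:
        """Symmetric to overlaps_3prime via the reverse complement; the
        returned overhangs are on the positive strand, 5' of the contig."""
        flipped = self.overlaps_3prime(revcomp(contig))
        out = []
        for h in flipped:
            out.append(
                OverlapHit(
                    h.read_id,
                    "-" if h.strand == "+" else "+",
                    h.overlap_length,
                    revcomp(h.overhang),
                )
            )
        return out


def find_overlapping_reads(
    contig_end_sequence: str,
    reads: Iterable[FastqRecord],
    min_overlap: int = 31,
) -> list[OverlapHit]:
    """Convenience one-shot form: hits whose exact overlap ends at the 3'
    terminus of `contig_end_sequence`. Builds a fresh index; for iterative
    use, construct a ReadIndex once."""
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    return ReadIndex(reads, min_overlap).overlaps_3prime(contig_end_sequence)


def _consensus_overhang(
    overhangs: Sequence[str],
    min_support: int,
    consensus_fraction: float,
    ties: list[str],
    end_label: str,
) -> tuple[str, list[int]]:
    """Column-by-column consensus of stacked overhangs; stops at the first
    column failing support or agreement, or at a top-count tie."""
    added: list[str] = []
    support: list[int] = []
    col = 0
    while True:
        column = [o[col] for o in overhangs if len(o) > col]
        if len(column) < min_support:
            break
        counts = Counter(column)
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            ties.append(f"{end_label}+{col}: tie {ranked[0][0]}/{ranked[1][0]}")
            break
        base, top = ranked[0]
        if top / len(column) < consensus_fraction:
            break
        added.append(base)
        support.append(len(column))
        col += 1
    return "".join(added), support


def extend_once(
    contig: str,
    hits5: Sequence[OverlapHit],
    hits3: Sequence[OverlapHit],
    min_support: int = 3,
    consensus_fraction: float = 0.8,
    round_index: int = 0,
) -> tuple[str, ExtensionRound]:
    """One extension round over precomputed hits for both ends."""
    ties: list[str] = []
    added3, support3 = _consensus_overhang(
        [h.overhang for h in hits3], min_support, consensus_fraction, ties, "3'"
    )
    # 5' overhangs grow away from the contig start; consensus is computed on
    # the reversed strings so column 0 abuts the contig
    added5_rev, support5 = _consensus_overhang(
        [h.overhang[::-1] for h in hits5], min_support, consensus_fraction, ties, "5'"
    )
    added5 = added5_rev[::-1]
    rnd = ExtensionRound(round_index, added5, added3, support5, support3, ties)
    return added5 + contig + added3, rnd


def iterate_extension(
    contig: str,
    reads: Iterable[FastqRecord],
    config: PipelineConfig | None = None,
) -> tuple[str, list[ExtensionRound]]:
    """Repeat extension until a full round adds nothing at either end.

    The final sequence always contains the input contig as an exact
    substring; non-convergence at max_rounds returns the partial result
    with a warning.
    """
    cfg = config or PipelineConfig()
    index = ReadIndex(reads, cfg.min_overlap)
    rounds: list[ExtensionRound] = []
    current = contig
    for i in range(cfg.max_rounds):
        hits3 = index.overlaps_3prime(current)
        hits5 = index.overlaps_5prime(current)
        current, rnd = extend_once(
            current, hits5, hits3, cfg.min_support, cfg.consensus_fraction, i
        )
        rounds.append(rnd)
        if rnd.bases_added == 0:
            break
    else:
        log.warning("extension did not converge within %d rounds", cfg.max_rounds)
    return current, rounds


@dataclass
class CoverageConsensus:
    depth: np.ndarray  # per-base read depth
    majority: str  # per-base majority call ('.' where depth 0)
    agreement: np.ndarray  # majority fraction per base (0 where depth 0)
    consensus: str  # curated sequence
    n_mapped: int
    n_unmapped: int
    changes: list[tuple[int, str, str]]  # (position, ref, new)
    zero_coverage: list[int]


_BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_IDX_TO_BASE = "ACGTN"


def _place_read(
    seq: str,
    genome: str,
    seed_index: dict[str, list[int]],
    w: int,
    max_mismatches: int,
) -> tuple[int, int] | None:
    """Best ungapped placement (start, mismatches) of an oriented read, or
    None. Seeds are taken at offsets 0, w, 2w, ... so one error cannot kill
    every seed of a read longer than 2w."""
    G = len(genome)
    best: tuple[int, int] | None = None
    seen: set[int] = set()
    for off in range(0, len(seq) - w + 1, w):
        seed = seq[off : off + w]
        for p in seed_index.get(seed, ()):
            start = p - off
            if start < 0 or start + len(seq) > G or start in seen:
                continue
            seen.add(start)
            mism = 0
            for a, b in zip(seq, genome[start : start + len(seq)]):
                if a != b and a != "N":
                    mism += 1
                    if mism > max_mismatches:
                        break
            else:
                if best is None or mism < best[1]:
                    best = (start, mism)
    return best


def map_and_consensus(
    reads: Iterable[FastqRecord],
    genome: str,
    seed_length: int = 31,
    max_mismatches: int = 3,
    consensus_fraction: float = 0.8,
) -> CoverageConsensus:
    """Map reads by exact seed + ungapped verification; compute depth,
    per-base majority, and a curated consensus.

    The consensus differs from the input only at positions where agreement
    >= consensus_fraction and the majority base is not the reference base.
    """
    G = len(genome)
    if G < seed_length:
        raise ValueError("genome shorter than seed_length")
    seed_index: dict[str, list[int]] = {}
    for i in range(G - seed_length + 1):
        seed_index.setdefault(genome[i : i + seed_length], []).append(i)

    counts = np.zeros((G, 5), dtype=np.int32)
    n_mapped = 0
    n_unmapped = 0
    for read in sorted(reads, key=lambda r: r.id):
        placed: tuple[int, int, str] | None = None
        for strand in ("+", "-"):
            seq = read.bases if strand == "+" else revcomp(read.bases)
            if len(seq) < seed_length:
                continue
            hit = _place_read(seq, genome, seed_index, seed_length, max_mismatches)
            if hit and (placed is None or hit[1] < placed[1]):
                placed = (hit[0], hit[1], strand)
        if placed is None:
            n_unmapped += 1
            continue
        n_mapped += 1
        start, _, strand = placed
        seq = read.bases if strand == "+" else revcomp(read.bases)
        idx = np.fromiter((_BASE_TO_IDX[b] for b in seq), dtype=np.int64)
        np.add.at(counts, (np.arange(start, start + len(seq)), idx), 1)

    acgt = counts[:, :4]
    depth = acgt.sum(axis=1)
    top_idx = acgt.argmax(axis=1)
    top_n = acgt[np.arange(G), top_idx]
    agreement = np.where(depth > 0, top_n / np.maximum(depth, 1), 0.0)
    majority_chars = []
    consensus_chars = []
    changes: list[tuple[int, str, str]] = []
    zero_cov: list[int] = []
    for i in range(G):
        ref = genome[i]
        if depth[i] == 0:
            majority_chars.append(".")
            consensus_chars.append(ref)
            zero_cov.append(i)
            continue
        # an exact top-count tie is not a majority call: keep the reference
        tied = (acgt[i] == top_n[i]).sum() > 1
        maj = ref if tied else _IDX_TO_BASE[top_idx[i]]
        majority_chars.append(maj)
        if maj != ref and agreement[i] >= consensus_fraction:
            consensus_chars.append(maj)
            changes.append((i, ref, maj))
        else:
            consensus_chars.append(ref)
    if changes:
        log.info("consensus changed %d position(s)", len(changes))
    return CoverageConsensus(
        depth=depth,
        majority="".join(majority_chars),
        agreement=agreement,
        consensus="".join(consensus_chars),
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        changes=changes,
        zero_coverage=zero_cov,
    )
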