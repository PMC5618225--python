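"""A small de Bruijn assembler for 1-3 kb genomes at high coverage.

K-mers are strand-canonical (a k-mer and its reverse complement are one
node) because dsRNA libraries sequence both strands evenly. Contigs are
maximal non-branching paths; low-coverage short tips hanging off junctions
are pruned once before path extraction. k must be odd so no k-mer can be
its own reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._dna import canonical, revcomp
from .io import FastqRecord

log = logging.getLogger(__name__)

_BASES = "ACGT"


class EmptyGraphError(ValueError):
    """No k-mer survived coverage pruning."""


@dataclass
class Contig:
    sequence: str
    mean_kmer_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


class DeBruijnGraph:
    """Canonical k-mer multiset with (k-1)-overlap adjacency."""

    def __init__(self, k: int, counts: dict[str, int]):
        self.k = k
        self.counts = counts

    def __len__(self) -> int:
        return len(self.counts)

    def has(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def count(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def forward(self, kmer: str) -> list[str]:
        """Oriented successors sharing a (k-1)-overlap, lexicographic order."""
        suf = kmer[1:]
        return [suf + b for b in _BASES if canonical(suf + b) in self.counts]

    def backward(self, kmer: str) -> list[str]:
        pre = kmer[:-1]
        return [b + pre for b in _BASES if canonical(b + pre) in self.counts]


def build_graph(
    reads: Iterable[FastqRecord | str], k: int = 31, min_kmer_coverage: int = 2
) -> DeBruijnGraph:
    """Count canonical k-mers over all reads and prune multiplicity <
    min_kmer_coverage (substitution-error k-mers are mostly singletons).

    Raises EmptyGraphError when nothing survives.
    """
    if k % 2 == 0 or not (15 <= k <= 99):
        raise ValueError("k must be odd and in [15, 99]")
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.bases if isinstance(read, FastqRecord) else read
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ckmer = canonical(kmer)
            counts[ckmer] = counts.get(ckmer, 0) + 1
    counts = {km: c for km, c in counts.items() if c >= min_kmer_coverage}
    if not counts:
        raise EmptyGraphError(
            f"no k-mer reached multiplicity {min_kmer_coverage} at k={k}"
        )
    return DeBruijnGraph(k, counts)


def _extract_unitigs(graph: DeBruijnGraph) -> list[Contig]:
    """Maximal non-branching paths, each reported in canonical orientation."""
    k = graph.k
    visited: set[str] = set()
    unitigs: list[Contig] = []
    for start in sorted(graph.counts):
        if start in visited:
            continue
        visited.add(start)
        seq = start
        covs = [graph.counts[start]]
        # extend to the right
        cur = start
        while True:
            nxts = graph.forward(cur)
            if len(nxts) != 1:
                break
            nxt = nxts[0]
            if canonical(nxt) in visited or len(graph.backward(nxt)) != 1:
                break
            visited.add(canonical(nxt))
            seq += nxt[-1]
            covs.append(graph.count(nxt))
            cur = nxt
        # extend to the left
        cur = start
        while True:
            prevs = graph.backward(cur)
            if len(prevs) != 1:
                break
            prv = prevs[0]
            if canonical(prv) in visited or len(graph.forward(prv)) != 1:
                break
            visited.add(canonical(prv))
            seq = prv[0] + seq
            covs.insert(0, graph.count(prv))
            cur = prv
        rc = revcomp(seq)
        unitigs.append(Contig(min(seq, rc), sum(covs) / len(covs)))
    unitigs.sort(key=lambda c: (-c.length, c.sequence))
    return unitigs


def _tip_kmers(graph: DeBruijnGraph, unitigs: Sequence[Contig]) -> set[str]:
    """Canonical k-mers of short, low-coverage dead-end unitigs.

    A tip is shorter than 2k, dead at one end, attached at the other, and
    has mean coverage below 25% of the best coverage entering the junction.
    """
    k = graph.k
    tips: set[str] = set()
    for u in unitigs:
        if u.length >= 2 * k:
            continue
        seq = u.sequence
        first, last = seq[:k], seq[-k:]
        dead_fwd = not graph.forward(last)
        dead_bwd = not graph.backward(first)
        if dead_fwd == dead_bwd:  # island or internal segment, not a tip
            continue
        junction = graph.backward(first) if dead_fwd else graph.forward(last)
        neighbour_cov = max(graph.count(n) for n in junction)
        if u.mean_kmer_coverage < 0.25 * neighbour_cov:
            tips.update(
                canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)
            )
    return tips


def assemble(graph: DeBruijnGraph, tip_removal: bool = True) -> list[Contig]:
    """Emit contigs (maximal non-branching paths) in deterministic order:
    by length descending, then lexicographic."""
    if not graph.counts:
        raise EmptyGraphError("cannot assemble an empty graph")
    unitigs = _extract_unitigs(graph)
    if tip_removal:
        tips = _tip_kmers(graph, unitigs)
        if tips:
            pruned = {km: c for km, c in graph.counts.items() if km not in tips}
            if pruned:
                log.info("tip removal pruned %d k-mers", len(tips))
                unitigs = _extract_unitigs(DeBruijnGraph(graph.k, pruned))
    return unitigs


def filter_contigs(contigs: Sequence[Contig], min_length: int = 300) -> list[Contig]:
    """Drop contigs shorter than min_length (boundary: min_length is kept)."""
    kept = [c for c in contigs if c.length >= min_length]
    removed = len(contigs) - len(kept)
    if removed:
        log.warning("removed %d contig(s) shorter than %d nt", removed, min_length)
    return kept
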