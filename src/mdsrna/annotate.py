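"""Genome anatomy: anchored coordinates, poly(A) runs, preprotoxin ORF
features, and the 3'-terminal stem-loop scan.

Coordinate convention: positions are reported relative to the conserved
5'-GAAAAA motif. The G of the anchor is position 1; bases upstream are
labelled (-)1, (-)2, ... outward; bases downstream of the legacy 3' end
(the classically accepted terminus, e.g. CCTAGC for the K2 toxin genome)
are labelled (+)1, (+)2, ... There is no position 0. Internally everything
is 0-based half-open; the signed labels exist only at the reporting
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.Seq import Seq

from ._thermo import hairpin_energy_kj, is_pair

ANCHOR_MOTIF = "GAAAAA"


# --------------------------------------------------------------------------
# signed anchored coordinates


@dataclass(frozen=True)
class AnchoredCoord:
    """Signed, zero-free position label: (-)n upstream of the anchor, n in
    the legacy genome, (+)n past the legacy 3' end."""

    n: int
    cls: str = "core"  # minus | core | plus

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("label ordinal must be >= 1 (there is no position 0)")
        if self.cls not in ("minus", "core", "plus"):
            raise ValueError(f"unknown coordinate class {self.cls!r}")

    def __str__(self) -> str:
        if self.cls == "minus":
            return f"(-){self.n}"
        if self.cls == "plus":
            return f"(+){self.n}"
        return str(self.n)


def to_paper_coord(
    index: int, anchor_index: int, legacy3_index: int | None = None
) -> AnchoredCoord:
    """Map a 0-based index to its signed label.

    anchor_index maps to 1; anchor_index-1 to (-)1; indices past
    legacy3_index (0-based index of the last legacy base) map to (+)1, ...
    """
    if index < 0:
        raise ValueError("index must be non-negative")
    if index < anchor_index:
        return AnchoredCoord(anchor_index - index, "minus")
    if legacy3_index is not None and index > legacy3_index:
        return AnchoredCoord(index - legacy3_index, "plus")
    return AnchoredCoord(index - anchor_index + 1, "core")


def from_paper_coord(
    coord: AnchoredCoord | str, anchor_index: int, legacy3_index: int | None = None
) -> int:
    """Inverse of to_paper_coord (round-trip identity)."""
    if isinstance(coord, str):
        coord = parse_paper_coord(coord)
    if coord.cls == "minus":
        return anchor_index - coord.n
    if coord.cls == "plus":
        if legacy3_index is None:
            raise ValueError("(+) labels need a legacy 3'-end index")
        return legacy3_index + coord.n
    return anchor_index + coord.n - 1


_COORD_RE = re.compile(r"^\((?P<sign>[-+−])\)(?P<n>\d+)$|^(?P<plain>\d+)$")


def parse_paper_coord(text: str) -> AnchoredCoord:
    m = _COORD_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse coordinate label {text!r}")
    if m.group("plain"):
        return AnchoredCoord(int(m.group("plain")), "core")
    cls = "plus" if m.group("sign") == "+" else "minus"
    return AnchoredCoord(int(m.group("n")), cls)


# --------------------------------------------------------------------------
# anchor location


def find_orf(genome: str, min_codons: int = 60) -> Optional[tuple[int, int]]:
    """Longest forward ORF (ATG..stop, stop included) whose start codon lies
    in the 5' third of the genome; None when no ORF reaches min_codons."""
    stops = {"TAA", "TAG", "TGA"}
    limit = len(genome) // 3
    best: tuple[int, int] | None = None
    for m in re.finditer("ATG", genome):
        s = m.start()
        if s > limit:
            break
        for e in range(s + 3, len(genome) - 2, 3):
            if genome[e : e + 3] in stops:
                if (e + 3 - s) // 3 - 1 >= min_codons:
                    if best is None or e + 3 - s > best[1] - best[0]:
                        best = (s, e + 3)
                break
    return best


def locate_anchor(
    genome: str,
    orf_hint: int | None = None,
    policy: str = "orf_proximal",
) -> Optional[int]:
    """0-based index of the G of the GAAAAA occurrence chosen as anchor.

    With policy 'orf_proximal' (default) the occurrence nearest upstream of
    the ORF start is chosen; 'first' takes the leftmost occurrence. Returns
    None (absence, not an error) when the motif does not occur.
    """
    occurrences = [m.start() for m in re.finditer(f"(?={ANCHOR_MOTIF})", genome)]
    if not occurrences:
        return None
    if policy == "first":
        return occurrences[0]
    if policy != "orf_proximal":
        raise ValueError(f"unknown anchor policy {policy!r}")
    orf_start = orf_hint
    if orf_start is None:
        orf = find_orf(genome)
        orf_start = orf[0] if orf else None
    if orf_start is not None:
        upstream = [i for i in occurrences if i <= orf_start]
        if upstream:
            return upstream[-1]
    return occurrences[0]


# --------------------------------------------------------------------------
# poly(A) runs


@dataclass
class PolyARun:
    start: int
    end: int  # half-open
    a_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


def find_polyA_runs(
    genome: str,
    min_run: int = 12,
    purity: float = 0.9,
    interior_margin: int = 50,
) -> list[PolyARun]:
    """Maximal interior A-rich intervals, 5'->3', non-overlapping.

    An interval must begin and end on A, have A fraction >= purity and
    length >= min_run. For every candidate start the longest qualifying
    window is taken; overlapping candidates are resolved longest-first
    (ties to the leftmost). Runs within `interior_margin` nt of a terminus
    are not "central" and are dropped.
    """
    import numpy as np

    n = len(genome)
    is_a = np.frombuffer(genome.encode(), dtype=np.uint8) == ord("A")
    prefix = np.concatenate(([0], np.cumsum(is_a)))
    # f[j] = A-count(0..j) - purity*j; window [i, j) qualifies iff f[j] >= f[i]
    f = prefix - purity * np.arange(n + 1)
    ends_on_a = np.concatenate(([False], is_a))  # j is a valid end iff seq[j-1]=='A'
    candidates: list[tuple[int, int]] = []
    for i in range(n):
        if not is_a[i] or (i > 0 and is_a[i - 1]):
            continue  # starts only at the first A of a pure run
        js = np.nonzero((f[i + min_run :] >= f[i] - 1e-9) & ends_on_a[i + min_run :])[0]
        if js.size:
            candidates.append((i, i + min_run + int(js[-1])))
    chosen: list[tuple[int, int]] = []
    for s, e in sorted(candidates, key=lambda c: (c[0] - c[1], c[0])):
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    out = []
    for s, e in sorted(chosen):
        if s >= interior_margin and e <= n - interior_margin:
            out.append(PolyARun(s, e, (prefix[e] - prefix[s]) / (e - s)))
    return out


# --------------------------------------------------------------------------
# preprotoxin ORF features


@dataclass
class PreprotoxinFeatures:
    orf_start: int  # 0-based, half-open interval includes the stop codon
    orf_end: int
    frame: int
    protein: str
    kex2_sites: list[int] = field(default_factory=list)  # 1-based aa pos of
    # the second (R) residue of each dibasic pair; cleavage occurs after it
    nglyc_sites: list[int] = field(default_factory=list)  # 1-based aa pos of N
    signal_cleavage_aa: int | None = None  # user-supplied, reported only
    terminal_kr_note: str = ""


def scan_kex2_sites(protein: str) -> list[int]:
    """1-based positions of the R of every dibasic (K|R)R pair; the Kex2
    endopeptidase cleaves after the pair."""
    return [i + 1 for i in range(1, len(protein)) if protein[i] == "R" and protein[i - 1] in "KR"]


def scan_nglyc_sites(protein: str) -> list[int]:
    """1-based positions of N in every N-X-[S/T] sequon with X != P."""
    return [
        i + 1
        for i in range(len(protein) - 2)
        if protein[i] == "N" and protein[i + 1] != "P" and protein[i + 2] in "ST"
    ]


def annotate_preprotoxin(
    genome: str,
    anchor: int | None = None,
    min_codons: int = 60,
    signal_cleavage_aa: int | None = None,
) -> Optional[PreprotoxinFeatures]:
    """Locate and annotate the preprotoxin ORF; None when no ORF reaches
    min_codons ("no ORF" status, not an error)."""
    orf = find_orf(genome, min_codons)
    if orf is None:
        return None
    s, e = orf
    protein = str(Seq(genome[s : e - 3]).translate())
    note = ""
    if protein and protein[-1] in "KR":
        note = (
            f"C-terminal {protein[-1]} is a candidate Kex1 carboxypeptidase "
            "trimming substrate"
        )
    return PreprotoxinFeatures(
        orf_start=s,
        orf_end=e,
        frame=s % 3,
        protein=protein,
        kex2_sites=scan_kex2_sites(protein),
        nglyc_sites=scan_nglyc_sites(protein),
        signal_cleavage_aa=signal_cleavage_aa,
        terminal_kr_note=note,
    )


# --------------------------------------------------------------------------
# 3' stem-loop (TRE) scan


@dataclass
class StemLoop:
    arm5_start: int  # genome coordinates, half-open intervals
    arm5_end: int
    arm3_start: int
    arm3_end: int
    stem_length: int
    loop_length: int
    dG_kj: float


def scan_tre_stemloop(
    genome: str,
    window_3prime: int = 120,
    min_stem: int = 4,
    wobble: bool = False,
) -> Optional[StemLoop]:
    """Exhaustively enumerate hairpins in the 3'-terminal window and return
    the minimum-free-energy one, or None if nothing folds below 0.

    Arms must pair base-by-base (Watson-Crick; G.U allowed when wobble=True)
    with a loop of at least 3 nt; each candidate is scored with the
    nearest-neighbour stack sum plus a linear loop penalty.
    """
    win_start = max(0, len(genome) - window_3prime)
    w = genome[win_start:].replace("T", "U")
    L = len(w)
    best: tuple[float, StemLoop] | None = None
    for a in range(L):
        for b in range(a + 2 * min_stem + 2, L):
            pairs: list[tuple[str, str]] = []
            k = 0
            while (
                b - k - (a + k) - 1 >= 3
                and is_pair(w[a + k], w[b - k], wobble)
            ):
                pairs.append((w[a + k], w[b - k]))
                k += 1
            if k < min_stem:
                continue
            loop_len = b - a - 2 * k + 1
            dg = hairpin_energy_kj(pairs, loop_len)
            if dg >= 0:
                continue
            cand = StemLoop(
                arm5_start=win_start + a,
                arm5_end=win_start + a + k,
                arm3_start=win_start + b - k + 1,
                arm3_end=win_start + b + 1,
                stem_length=k,
                loop_length=loop_len,
                dG_kj=dg,
            )
            if best is None or dg < best[0]:
                best = (dg, cand)
    return best[1] if best else None


# --------------------------------------------------------------------------
# whole-genome annotation and GFF3 output


@dataclass
class GenomeAnnotation:
    genome_id: str
    length: int
    anchor: int | None
    orf: PreprotoxinFeatures | None
    polya: list[PolyARun]
    stemloop: StemLoop | None
    legacy3_index: int | None  # 0-based index of last legacy base
    extra5: tuple[int, int] | None
    extra3: tuple[int, int] | None


def annotate_genome(
    genome: str,
    genome_id: str = "genome",
    legacy3_motif: str | None = None,
    polya_min_run: int = 12,
    polya_purity: float = 0.9,
    hairpin_window: int = 120,
    min_stem: int = 4,
    wobble: bool = False,
    anchor_policy: str = "orf_proximal",
    signal_cleavage_aa: int | None = None,
) -> GenomeAnnotation:
    """Run the full anatomy scan on one positive-strand genome.

    legacy3_motif is the classically accepted 3'-terminal sequence for this
    virus (e.g. CCTAGC for the K2 toxin genome); its rightmost occurrence
    defines the boundary past which positions are labelled (+)n and the
    3'-extra interval.
    """
    orf = annotate_preprotoxin(genome, signal_cleavage_aa=signal_cleavage_aa)
    anchor = locate_anchor(
        genome, orf_hint=orf.orf_start if orf else None, policy=anchor_policy
    )
    legacy3 = None
    extra3 = None
    if legacy3_motif:
        idx = genome.rfind(legacy3_motif)
        if idx != -1:
            legacy3 = idx + len(legacy3_motif) - 1
            if legacy3 + 1 < len(genome):
                extra3 = (legacy3 + 1, len(genome))
    extra5 = (0, anchor) if anchor else None
    return GenomeAnnotation(
        genome_id=genome_id,
        length=len(genome),
        anchor=anchor,
        orf=orf,
        polya=find_polyA_runs(genome, polya_min_run, polya_purity),
        stemloop=scan_tre_stemloop(genome, hairpin_window, min_stem, wobble),
        legacy3_index=legacy3,
        extra5=extra5,
        extra3=extra3,
    )


def _gff_line(
    seqid: str,
    ftype: str,
    start0: int,
    end0: int,
    anchor: int | None,
    legacy3: int | None,
    attrs: str = "",
    score: str = ".",
) -> str:
    paper = ""
    if anchor is not None:
        lo = to_paper_coord(start0, anchor, legacy3)
        hi = to_paper_coord(end0 - 1, anchor, legacy3)
        paper = f"paper_coord={lo}..{hi};"
    extra = attrs + ";" if attrs and not attrs.endswith(";") else attrs
    return (
        f"{seqid}\tmdsrna\t{ftype}\t{start0 + 1}\t{end0}\t{score}\t+\t.\t{extra}{paper}"
    ).rstrip(";")


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    a = annotation
    lines = ["##gff-version 3", f"##sequence-region {a.genome_id} 1 {a.length}"]

    def add(ftype: str, s: int, e: int, attrs: str = "", score: str = ".") -> None:
        lines.append(
            _gff_line(a.genome_id, ftype, s, e, a.anchor, a.legacy3_index, attrs, score)
        )

    if a.anchor is not None:
        add("anchor", a.anchor, a.anchor + 6, "Name=GAAAAA")
    if a.extra5 and a.extra5[1] > a.extra5[0]:
        add("extra5", *a.extra5)
    if a.extra3:
        add("extra3", *a.extra3)
    if a.orf:
        add("ORF", a.orf.orf_start, a.orf.orf_end, f"length_aa={len(a.orf.protein)}")
        if a.orf.signal_cleavage_aa:
            cut = a.orf.orf_start + 3 * a.orf.signal_cleavage_aa
            add("signal_note", a.orf.orf_start, cut, "Note=user-supplied cleavage")
        for pos in a.orf.kex2_sites:
            s = a.orf.orf_start + 3 * (pos - 2)
            add("kex2_site", s, s + 6, f"aa={pos - 1}-{pos}")
        for pos in a.orf.nglyc_sites:
            s = a.orf.orf_start + 3 * (pos - 1)
            add("nglyc_site", s, s + 9, f"aa={pos}")
    for run in a.polya:
        add("polyA", run.start, run.end, f"a_fraction={run.a_fraction:.3f}")
    if a.stemloop:
        sl = a.stemloop
        add(
            "stem_loop",
            sl.arm5_start,
            sl.arm3_end,
            f"stem={sl.stem_length};loop={sl.loop_length}",
            score=f"{sl.dG_kj:.1f}",
        )
    Path(path).write_text("\n".join(lines) + "\n")
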