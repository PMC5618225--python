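"""Read filtering: trim terminal poly-N, then drop reads that are too short
(< 50 nt), too ambiguous (>= 5% N), or low quality (mean phred < 28).

Each discarded read is attributed to exactly one failure cause, tested in
the fixed order trim -> length -> N fraction -> quality, so the report is
deterministic. Filtering is idempotent: a read that passes once passes again
unchanged.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .config import PipelineConfig
from .io import FastqRecord


@dataclass
class QcReport:
    input_reads: int = 0
    passed_reads: int = 0
    failed_by_length: int = 0
    failed_by_n_fraction: int = 0
    failed_by_quality: int = 0
    bases_trimmed_polyN: int = 0

    def check(self) -> None:
        total = (
            self.passed_reads
            + self.failed_by_length
            + self.failed_by_n_fraction
            + self.failed_by_quality
        )
        if total != self.input_reads:
            raise AssertionError("QC tallies do not add up to input read count")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            for k, v in vars(self).items():
                w.writerow([k, v])


def trim_polyN(read: FastqRecord) -> FastqRecord:
    """Remove maximal terminal N runs from both ends (interior Ns kept);
    qualities are trimmed in step. May return an empty read."""
    bases = read.bases
    start = 0
    end = len(bases)
    while start < end and bases[start] == "N":
        start += 1
    while end > start and bases[end - 1] == "N":
        end -= 1
    if start == 0 and end == len(bases):
        return read
    return FastqRecord(read.id, bases[start:end], read.qualities[start:end])


def _quality_stat(read: FastqRecord, statistic: str) -> float:
    if not read.qualities:
        return 0.0
    if statistic == "min":
        return float(min(read.qualities))
    return read.mean_quality


def filter_reads(
    reads: Iterable[FastqRecord], config: PipelineConfig | None = None
) -> tuple[list[FastqRecord], QcReport]:
    """Apply trim + three filters; returns surviving reads and the tally.

    Boundary semantics: a read fails iff length < min_length, iff
    N fraction >= max_n_fraction ("at least 5%"), iff quality statistic
    < min_mean_phred. Thus 50 nt passes, exactly 5% N fails, mean 28 passes.
    """
    cfg = config or PipelineConfig()
    report = QcReport()
    passed: list[FastqRecord] = []
    for read in reads:
        report.input_reads += 1
        trimmed = trim_polyN(read)
        report.bases_trimmed_polyN += len(read) - len(trimmed)
        if len(trimmed) < cfg.min_length:
            report.failed_by_length += 1
            continue
        if trimmed.n_fraction() >= cfg.max_n_fraction:
            report.failed_by_n_fraction += 1
            continue
        if _quality_stat(trimmed, cfg.quality_statistic) < cfg.min_mean_phred:
            report.failed_by_quality += 1
            continue
        report.passed_reads += 1
        passed.append(trimmed)
    report.check()
    return passed, report


def filter_stream(
    reads: Iterable[FastqRecord], config: PipelineConfig, report: QcReport
) -> Iterator[FastqRecord]:
    """Streaming variant used by the CLI; mutates `report` in place."""
    for read in reads:
        report.input_reads += 1
        trimmed = trim_polyN(read)
        report.bases_trimmed_polyN += len(read) - len(trimmed)
        if len(trimmed) < config.min_length:
            report.failed_by_length += 1
        elif trimmed.n_fraction() >= config.max_n_fraction:
            report.failed_by_n_fraction += 1
        elif _quality_stat(trimmed, config.quality_statistic) < config.min_mean_phred:
            report.failed_by_quality += 1
        else:
            report.passed_reads += 1
            yield trimmed
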