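"""Raw-read cleanup for CLASH and small-RNA libraries.

Reads carry 4 random nucleotides (UMIs) at both ends plus a 3' sequencing
adapter.  Cleanup order is fixed: adapter trimming, then collapse of PCR
duplicates on the full (umi5, insert, umi3) triple, then the minimum-length
filter on the insert.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


@dataclass(frozen=True)
class CleanRead:
    """A deduplicated read insert with its two UMIs and duplicate count."""

    insert: str
    umi5: str
    umi3: str
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("CleanRead.copies must be >= 1")
        if len(self.umi5) != len(self.umi3):
            raise ValueError("UMI lengths differ")


@dataclass
class PreprocessReport:
    reads_in: int = 0
    adapter_trimmed: int = 0
    dropped_too_short_for_umis: int = 0
    molecules: int = 0
    dropped_below_min_length: int = 0
    reads_out: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


MIN_ADAPTER_OVERLAP = 5


def trim_adapter(read_sequence: str, adapter3: str) -> str:
    """Remove a 3' adapter: the longest read suffix that exactly matches a
    prefix of ``adapter3`` with >= 5 nt overlap.  No-op when absent;
    internal occurrences are not searched.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if read_sequence.endswith(adapter3):  # fast path: full adapter present
        return read_sequence[: -len(adapter3)]
    for k in range(min(len(read_sequence), len(adapter3) - 1), MIN_ADAPTER_OVERLAP - 1, -1):
        if read_sequence.endswith(adapter3[:k]):
            return read_sequence[:-k]
    return read_sequence


def collapse_clean(reads: list[CleanRead]) -> list[CleanRead]:
    """Merge CleanReads identical over (umi5, insert, umi3), summing copies.

    Idempotent; output sorted lexicographically by (insert, umi5, umi3).
    """
    acc: Counter[tuple[str, str, str]] = Counter()
    for r in reads:
        acc[(r.insert, r.umi5, r.umi3)] += r.copies
    return [
        CleanRead(insert, u5, u3, n)
        for (insert, u5, u3), n in sorted(acc.items())
    ]


def collapse_umi_duplicates(
    trimmed_reads: list[str], umi_len: int = 4, report: PreprocessReport | None = None
) -> list[CleanRead]:
    """Collapse adapter-trimmed reads that are identical over their full
    sequence (both UMIs + insert) into single molecules.

    Reads shorter than ``2 * umi_len + 1`` (no insert base left) are dropped
    and counted in the report.
    """
    min_len = 2 * umi_len + 1
    counts: Counter[str] = Counter()
    dropped = 0
    for seq in trimmed_reads:
        if len(seq) < min_len:
            dropped += 1
        else:
            counts[seq] += 1
    out = [
        CleanRead(seq[umi_len:-umi_len], seq[:umi_len], seq[-umi_len:], n)
        for seq, n in counts.items()
    ]
    out.sort(key=lambda r: (r.insert, r.umi5, r.umi3))
    if report is not None:
        report.dropped_too_short_for_umis += dropped
        report.molecules += len(out)
    return out


def filter_min_length(
    clean_reads: list[CleanRead], min_length: int = 18
) -> tuple[list[CleanRead], int]:
    """Drop inserts shorter than ``min_length`` (18 by default; an 18-nt
    insert is kept).  Returns (kept, n_removed)."""
    kept = [r for r in clean_reads if len(r.insert) >= min_length]
    return kept, len(clean_reads) - len(kept)


def preprocess_reads(
    raw_reads: list[str],
    adapter3: str,
    umi_len: int = 4,
    min_length: int = 18,
) -> tuple[list[CleanRead], PreprocessReport]:
    """Full cleanup: trim -> collapse -> length filter, with a count report."""
    report = PreprocessReport(reads_in=len(raw_reads))
    if adapter3:
        trimmed = []
        for seq in raw_reads:
            t = trim_adapter(seq, adapter3)
            if len(t) != len(seq):
                report.adapter_trimmed += 1
            trimmed.append(t)
    else:  # pre-trimmed input
        trimmed = list(raw_reads)
    collapsed = collapse_umi_duplicates(trimmed, umi_len, report)
    kept, removed = filter_min_length(collapsed, min_length)
    report.dropped_below_min_length = removed
    report.reads_out = len(kept)
    return kept, report
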