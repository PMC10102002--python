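"""Chimeric-read hybrid calling: split each clean read into a miRNA arm and
a target fragment, map the fragment to the transcriptome by exact match,
extend the target 25 nt at its 3' end, and aggregate per-site counts into
per-condition RPM and fold change.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io_formats import MiRNA, Transcript
from .preprocess import CleanRead
from .screen import DEFAULT_CONFIG, ScreenConfig

MIN_FRAGMENT_LEN = 12
MIN_CHIMERA_LEN = 30
MAX_UNTEMPLATED_TAIL = 3


@dataclass(frozen=True)
class ChimeraSplit:
    """A read partitioned into a miRNA arm and a target fragment."""

    mirna_id: str
    mirna_span: tuple[int, int]  # 0-based half-open on the read
    fragment: str
    order: str  # "mirna_first" | "mirna_last"


@dataclass(frozen=True)
class HybridRecord:
    """One mapped miRNA x target site observation in one library."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open, after 3' extension
    site_end: int
    read_count: int
    library_id: str


@dataclass(frozen=True)
class HybridSiteSummary:
    """A merged site with per-library counts and per-condition abundance."""

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    counts: dict  # library_id -> molecules
    ko_rpm: float
    control_rpm: float
    fold_change: float
    infinite_fold: bool  # control RPM was exactly 0 before the pseudocount


class KmerIndex:
    """Exact-substring lookup over a transcript set via a k-mer hash."""

    def __init__(self, transcripts: list[Transcript], k: int = 12):
        self.k = k
        self.transcripts = {t.id: t for t in transcripts}
        self.skipped: list[str] = []
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for t in transcripts:
            if len(t.sequence) < k:
                self.skipped.append(t.id)
                continue
            seq = t.sequence
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((t.id, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def build_kmer_index(transcripts: list[Transcript], k: int = 12) -> KmerIndex:
    return KmerIndex(transcripts, k)


def _match_mirna_prefix(insert: str, m: MiRNA, prefix_len: int) -> int:
    """Longest l >= prefix_len with insert[:l] == m.sequence[:l], else 0."""
    if insert[:prefix_len] != m.sequence[:prefix_len]:
        return 0
    l = prefix_len
    limit = min(len(m.sequence), len(insert))
    while l < limit and insert[l] == m.sequence[l]:
        l += 1
    return l


def split_chimera(
    read: CleanRead | str,
    mirna_set: list[MiRNA],
    prefix_len: int = 18,
) -> ChimeraSplit | None:
    """Locate a miRNA arm at either read end; the remainder is the fragment.

    The miRNA must match either with its first ``prefix_len`` nt at the read
    5' start (arm = the longest extension of that match) or with its full
    mature sequence ending at the read 3' end.  Among several matching
    miRNAs the longest match wins, ties broken lexicographically by id.
    Returns None (non-hybrid) when nothing matches or the fragment is short.
    """
    insert = read.insert if isinstance(read, CleanRead) else read
    if len(insert) < MIN_CHIMERA_LEN:
        return None
    best: tuple[int, str, ChimeraSplit] | None = None  # (-match_len, id, split)
    for m in sorted(mirna_set, key=lambda x: x.id):
        l = _match_mirna_prefix(insert, m, prefix_len)
        if l and len(insert) - l >= MIN_FRAGMENT_LEN:
            cand = ChimeraSplit(m.id, (0, l), insert[l:], "mirna_first")
            if best is None or (-l, m.id) < best[:2]:
                best = (-l, m.id, cand)
        if insert.endswith(m.sequence):
            l = len(m.sequence)
            if len(insert) - l >= MIN_FRAGMENT_LEN:
                cand = ChimeraSplit(
                    m.id, (len(insert) - l, len(insert)), insert[: len(insert) - l],
                    "mirna_last",
                )
                if best is None or (-l, m.id) < best[:2]:
                    best = (-l, m.id, cand)
    return best[2] if best else None


def map_fragment(fragment: str, index: KmerIndex) -> list[tuple[str, int, int]]:
    """Exact-substring placements of ``fragment``, k-mer seeded.

    Returns all (transcript_id, start, end) hits (0-based half-open),
    deduplicated and sorted; empty when the fragment has no exact hit.
    """
    if len(fragment) < index.k:
        return []
    hits = set()
    for tid, pos in index.hits(fragment[: index.k]):
        seq = index.transcripts[tid].sequence
        if seq[pos : pos + len(fragment)] == fragment:
            hits.add((tid, pos, pos + len(fragment)))
    return sorted(hits)


def extend_target_3prime(
    hit: tuple[int, int], transcript_length: int, n: int = 25
) -> tuple[int, int]:
    """Extend a site interval by up to ``n`` nt at its 3' end, clamped to the
    transcript end (compensates fragment 3' trimming)."""
    start, end = hit
    return start, min(end + n, transcript_length)


def call_hybrids(
    clean_reads: list[CleanRead],
    mirnas: list[MiRNA],
    index: KmerIndex,
    library_id: str,
    config: ScreenConfig = DEFAULT_CONFIG,
    _split_cache: dict | None = None,
) -> tuple[list[HybridRecord], dict]:
    """Split + map every clean read of one library and tally per-site counts.

    Each CleanRead counts as one molecule (PCR duplicates were already
    collapsed).  If mapping the full fragment fails, up to 3 nt are shaved
    from the fragment's miRNA-proximal end (untemplated tailing of the
    miRNA arm consumes read bases that are not part of the target).
    Fragments hitting several transcripts are resolved after a first pass:
    the transcript with the highest unambiguous hybrid support wins, ties
    broken lexicographically; such sites are flagged in the stats.
    """
    prefix_dict: dict[str, list[MiRNA]] = defaultdict(list)
    for m in mirnas:
        prefix_dict[m.sequence[: config.prefix_len]].append(m)
    for v in prefix_dict.values():
        v.sort(key=lambda m: m.id)
    suffix_dict: dict[str, list[MiRNA]] = defaultdict(list)
    for m in mirnas:
        suffix_dict[m.sequence[-config.prefix_len :]].append(m)
    for v in suffix_dict.values():
        v.sort(key=lambda m: m.id)

    def resolve(insert: str):
        """-> (mirna_id, [candidate (tid, start, end) hits]) or None; cached."""
        if len(insert) < MIN_CHIMERA_LEN:
            return None
        # miRNA at the 5' end: longest prefix match wins
        best = None
        for m in prefix_dict.get(insert[: config.prefix_len], []):
            l = _match_mirna_prefix(insert, m, config.prefix_len)
            if l and len(insert) - l >= MIN_FRAGMENT_LEN:
                if best is None or (-l, m.id) < best[:2]:
                    best = (-l, m.id, l, "mirna_first")
        if best is not None:
            neg_l, mid, l, _ = best
            for tail in range(0, MAX_UNTEMPLATED_TAIL + 1):
                frag = insert[l + tail :]
                if len(frag) < MIN_FRAGMENT_LEN:
                    break
                hits = map_fragment(frag, index)
                if hits:
                    return mid, hits
        # miRNA at the 3' end: full mature sequence as read suffix
        for m in suffix_dict.get(insert[-config.prefix_len :], []):
            if insert.endswith(m.sequence):
                frag = insert[: len(insert) - len(m.sequence)]
                if len(frag) >= MIN_FRAGMENT_LEN:
                    hits = map_fragment(frag, index)
                    if hits:
                        return m.id, hits
        return None

    cache = _split_cache if _split_cache is not None else {}
    stats = {
        "reads": len(clean_reads),
        "non_hybrid": 0,
        "unmapped": 0,
        "hybrid": 0,
        "ambiguous": 0,
    }
    per_read: list[tuple[str, list[tuple[str, int, int]]]] = []
    for r in clean_reads:
        if r.insert in cache:
            res = cache[r.insert]
        else:
            res = resolve(r.insert)
            cache[r.insert] = res
        if res is None:
            stats["non_hybrid"] += 1
            continue
        per_read.append(res)

    # ambiguity resolution: support from unambiguous reads
    support: dict[str, int] = defaultdict(int)
    for _, hits in per_read:
        if len(hits) == 1:
            support[hits[0][0]] += 1
    counts: dict[tuple[str, str, int, int], int] = defaultdict(int)
    for mid, hits in per_read:
        if len(hits) > 1:
            stats["ambiguous"] += 1
            # highest unambiguous support wins; ties to the smallest id
            hits = [min(hits, key=lambda h: (-support[h[0]], h[0]))]
        tid, start, end = hits[0]
        tlen = len(index.transcripts[tid].sequence)
        start, end = extend_target_3prime((start, end), tlen, config.extension)
        counts[(mid, tid, start, end)] += 1
        stats["hybrid"] += 1

    records = [
        HybridRecord(mid, tid, s, e, n, library_id)
        for (mid, tid, s, e), n in sorted(counts.items())
    ]
    return records, stats


def aggregate_hybrids(
    hybrid_records: list[HybridRecord],
    library_condition_map: dict[str, str],
    clean_totals: dict[str, int],
    config: ScreenConfig = DEFAULT_CONFIG,
    hybrid_totals: dict[str, int] | None = None,
) -> list[HybridSiteSummary]:
    """Merge nearby sites per (miRNA, transcript) and compute per-condition
    RPM and KO/control fold change.

    Sites whose intervals lie within ``config.merge_distance`` nt are merged
    (union interval, summed counts).  Per-condition RPM divides summed site
    counts by the condition's total clean reads (``clean_totals``; or total
    hybrid reads when ``config.rpm_denominator == 'hybrid_reads'``, in which
    case ``hybrid_totals`` must be given).  The fold change adds a
    pseudocount of ``config.rpm_pseudocount`` RPM to both conditions.
    Conditions must be named 'control' and 'ko'.
    """
    for lib in {r.library_id for r in hybrid_records}:
        if lib not in library_condition_map:
            raise ValueError(f"library {lib!r} missing from condition map")
    totals_src = clean_totals
    if config.rpm_denominator == "hybrid_reads":
        if hybrid_totals is None:
            raise ValueError("hybrid_totals required for rpm_denominator='hybrid_reads'")
        totals_src = hybrid_totals
    cond_totals: dict[str, int] = defaultdict(int)
    for lib, n in totals_src.items():
        cond_totals[library_condition_map[lib]] += n

    grouped: dict[tuple[str, str], list[HybridRecord]] = defaultdict(list)
    for r in hybrid_records:
        grouped[(r.mirna_id, r.transcript_id)].append(r)

    summaries: list[HybridSiteSummary] = []
    for (mid, tid), recs in sorted(grouped.items()):
        recs.sort(key=lambda r: (r.site_start, r.site_end, r.library_id))
        clusters: list[list[HybridRecord]] = []
        cur: list[HybridRecord] = []
        cur_end = -(10**9)
        for r in recs:
            if cur and r.site_start > cur_end + config.merge_distance:
                clusters.append(cur)
                cur = []
            cur.append(r)
            cur_end = max(cur_end, r.site_end)
        if cur:
            clusters.append(cur)
        for cl in clusters:
            counts: dict[str, int] = defaultdict(int)
            for r in cl:
                counts[r.library_id] += r.read_count
            start = min(r.site_start for r in cl)
            end = max(r.site_end for r in cl)
            by_cond: dict[str, int] = defaultdict(int)
            for lib, n in counts.items():
                by_cond[library_condition_map[lib]] += n
            rpm = {
                cond: 1e6 * by_cond.get(cond, 0) / cond_totals[cond]
                for cond in cond_totals
            }
            ko, ctrl = rpm.get("ko", 0.0), rpm.get("control", 0.0)
            p = config.rpm_pseudocount
            fold = (ko + p) / (ctrl + p)
            summaries.append(
                HybridSiteSummary(
                    mid, tid, start, end, dict(counts), ko, ctrl, fold,
                    infinite_fold=(ctrl == 0.0),
                )
            )
    return summaries
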