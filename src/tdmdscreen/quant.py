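"""Small-RNA quantification and count-matrix normalization.

miRNA read assignment follows the 18-nt 5'-prefix rule: a clean read counts
for a miRNA iff its first 18 nt equal the miRNA's first 18 nt, which makes
counting tolerant to 3' tailing/trimming (isomiRs).  Normalization is
reads-per-million and median-of-ratios size factors; differential effect
sizes are plain log2 fold changes with the baseMean expression filters
(200 for miRNAs, 100 for mRNAs).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MiRNA
from .preprocess import CleanRead

PREFIX_LEN = 18
BASEMEAN_MIN = {"mirna": 200.0, "mrna": 100.0}


@dataclass
class CountMatrix:
    """Genes x samples integer counts with an optional condition mapping."""

    df: pd.DataFrame
    condition_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.df.index.duplicated().any() or self.df.columns.duplicated().any():
            raise ValueError("duplicate gene or sample ids")
        if (self.df.values < 0).any():
            raise ValueError("negative counts")


def count_mirna_reads(
    clean_reads: list[CleanRead], mirna_set: list[MiRNA]
) -> tuple[pd.Series, dict]:
    """Per-miRNA molecule counts for one sample.

    Each CleanRead counts once (duplicates were collapsed to molecules);
    reads whose 18-nt prefix matches several miRNAs count once for each and
    are tallied as ambiguous in the report.  miRNAs shorter than 18 nt are
    excluded with a warning entry.
    """
    excluded = [m.id for m in mirna_set if len(m.sequence) < PREFIX_LEN]
    usable = [m for m in mirna_set if len(m.sequence) >= PREFIX_LEN]
    by_prefix: dict[str, list[str]] = defaultdict(list)
    for m in usable:
        by_prefix[m.sequence[:PREFIX_LEN]].append(m.id)
    counts = {m.id: 0 for m in usable}
    ambiguous = 0
    assigned = 0
    for r in clean_reads:
        ids = by_prefix.get(r.insert[:PREFIX_LEN])
        if not ids:
            continue
        assigned += 1
        if len(ids) > 1:
            ambiguous += 1
        for mid in ids:
            counts[mid] += 1
    report = {
        "reads": len(clean_reads),
        "assigned": assigned,
        "ambiguous": ambiguous,
        "excluded_mirnas": excluded,
    }
    return pd.Series(counts, dtype="int64"), report


def length_distribution(
    clean_reads: list[CleanRead],
    mirna: MiRNA,
    lengths: range = range(18, 27),
) -> tuple[pd.Series, bool]:
    """Fraction of reads assigned to ``mirna`` at each insert length in
    ``lengths`` (18-26 nt by default).  Returns (fractions, zero_flag);
    fractions sum to 1 unless no read in range is assigned."""
    prefix = mirna.sequence[:PREFIX_LEN]
    tally = {n: 0 for n in lengths}
    for r in clean_reads:
        n = len(r.insert)
        if n in tally and r.insert[:PREFIX_LEN] == prefix:
            tally[n] += 1
    total = sum(tally.values())
    if total == 0:
        return pd.Series({n: 0.0 for n in lengths}), True
    return pd.Series({n: c / total for n, c in tally.items()}), False


def rpm_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million per sample: each column rescaled to sum 10^6."""
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return df / totals * 1e6


def size_factors(df: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the genewise geometric mean across samples, restricted
    to genes with nonzero counts in every sample; each sample's factor is
    the median of its count/reference ratios over those genes.
    """
    counts = df.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ref = np.exp(np.log(counts[all_pos]).mean(axis=1))
    factors = np.median(counts[all_pos] / ref[:, None], axis=0)
    return pd.Series(factors, index=df.columns)


def normalize_counts(df: pd.DataFrame) -> pd.DataFrame:
    return df / size_factors(df)


def differential(
    matrix: CountMatrix | pd.DataFrame,
    condition_of: dict[str, str] | None = None,
    kind: str = "mirna",
) -> pd.DataFrame:
    """Per-gene baseMean, log2 fold change (ko vs control) and filter flag.

    baseMean is the mean of size-factor-normalized counts over all samples;
    log2fc = log2((mean_ko + 0.5) / (mean_control + 0.5)) on normalized
    counts; ``kept`` iff baseMean >= 200 (miRNA) or >= 100 (mRNA).
    """
    if kind not in BASEMEAN_MIN:
        raise ValueError(f"kind must be one of {sorted(BASEMEAN_MIN)}")
    if isinstance(matrix, CountMatrix):
        df = matrix.df
        condition_of = condition_of or matrix.condition_of
    else:
        df = matrix
    if condition_of is None:
        raise ValueError("condition_of is required")
    conds = {condition_of[s] for s in df.columns}
    if conds != {"control", "ko"}:
        raise ValueError("need samples in both conditions 'control' and 'ko'")
    for cond in ("control", "ko"):
        if sum(condition_of[s] == cond for s in df.columns) < 2:
            raise ValueError(f"need >= 2 samples in condition {cond!r}")
    norm = df / size_factors(df)
    ko_cols = [s for s in df.columns if condition_of[s] == "ko"]
    ctrl_cols = [s for s in df.columns if condition_of[s] == "control"]
    base_mean = norm.mean(axis=1)
    log2fc = np.log2((norm[ko_cols].mean(axis=1) + 0.5) / (norm[ctrl_cols].mean(axis=1) + 0.5))
    # tiny relative tolerance keeps the boundary inclusive under the float
    # round trip through the size factors
    threshold = BASEMEAN_MIN[kind] * (1.0 - 1e-12)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": log2fc,
            "kept": base_mean >= threshold,
        }
    )
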