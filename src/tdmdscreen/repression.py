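"""Target-repression analytics: canonical seed-match target prediction,
cumulative fold-change distributions over target sets, the two-sided
Mann-Whitney test, and the organ-normalized inverse-correlation analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MiRNA, Transcript

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# seed-match target prediction (canonical 8mer / 7mer-m8 / 7mer-A1 sites)


def predict_seed_targets(
    mirna: MiRNA, transcripts: list[Transcript]
) -> tuple[dict[str, str], list[str]]:
    """Canonical-site scan of each annotated 3'UTR.

    A transcript is a predicted target iff its 3'UTR contains, against the
    miRNA seed, an 8mer (perfect Watson-Crick match to positions 2-8 plus an
    A opposite position 1), a 7mer-m8 (match to 2-8) or a 7mer-A1 (match to
    2-7 plus the A).  G:U pairs do not count in site matching.  Returns
    (target -> best site class, ids skipped for missing UTR annotation).
    """
    m = mirna.sequence
    site_m8 = revcomp(m[1:8])  # matches miRNA positions 2-8
    site_8mer = site_m8 + "A"
    site_a1 = revcomp(m[1:7]) + "A"  # matches positions 2-7, then A
    targets: dict[str, str] = {}
    skipped: list[str] = []
    for t in transcripts:
        if t.cds_end is None:
            skipped.append(t.id)
            continue
        utr = t.utr3
        if site_8mer in utr:
            targets[t.id] = "8mer"
        elif site_m8 in utr:
            targets[t.id] = "7mer-m8"
        elif site_a1 in utr:
            targets[t.id] = "7mer-A1"
    return targets, skipped


@dataclass(frozen=True)
class TargetSets:
    """The five gene groups compared in the repression analysis."""

    all_predicted: frozenset[str]
    conserved_predicted: frozenset[str]
    clash_targets: frozenset[str]
    overlap: frozenset[str]
    non_targets: frozenset[str]

    @classmethod
    def build(
        cls,
        all_predicted: set[str],
        conserved_predicted: set[str],
        clash_targets: set[str],
        universe: set[str],
    ) -> "TargetSets":
        overlap = clash_targets & all_predicted
        non_targets = universe - all_predicted - conserved_predicted - clash_targets
        return cls(
            frozenset(all_predicted),
            frozenset(conserved_predicted),
            frozenset(clash_targets),
            frozenset(overlap),
            frozenset(non_targets),
        )

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "all_predicted": self.all_predicted,
            "conserved_predicted": self.conserved_predicted,
            "clash_targets": self.clash_targets,
            "overlap": self.overlap,
            "non_targets": self.non_targets,
        }


@dataclass(frozen=True)
class CfcCurve:
    """Empirical CDF of per-gene log2 fold changes for one gene set."""

    set_name: str
    values: tuple[float, ...]  # sorted log2fc of kept genes
    median: float
    n: int
    low_n: bool

    def cdf(self, x: float) -> float:
        if self.n == 0:
            return 0.0
        return float(np.searchsorted(self.values, x, side="right")) / self.n


LOW_N = 5


def cumulative_fold_change(
    diff_results: pd.DataFrame, target_sets: TargetSets
) -> dict[str, CfcCurve]:
    """One CFC curve per target set over the baseMean-kept genes."""
    kept = diff_results[diff_results["kept"]]
    curves = {}
    for name, ids in target_sets.as_dict().items():
        vals = np.sort(kept.loc[kept.index.isin(ids), "log2fc"].to_numpy())
        curves[name] = CfcCurve(
            name,
            tuple(float(v) for v in vals),
            float(np.median(vals)) if len(vals) else math.nan,
            len(vals),
            len(vals) < LOW_N,
        )
    return curves


# ---------------------------------------------------------------------------
# Mann-Whitney U, two-sided

EXACT_MIN_N = 8  # exact permutation null when min(n1, n2) <= 8 ...
EXACT_MAX_TOTAL = 1000  # ... and the pooled sample is small enough to tabulate


def _exact_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation null of U with midranks (handles ties).

    Tabulates, by dynamic programming over doubled midranks, the number of
    n1-subsets at each possible rank sum; the two-sided P is the null
    probability of a |U - n1*n2/2| deviation at least as large as observed.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    N = n1 + n2
    r2 = np.round(2 * stats.rankdata(pooled)).astype(np.int64)
    s_obs = int(r2[:n1].sum())
    u_obs = s_obs / 2 - n1 * (n1 + 1) / 2
    # table[k, s]: number of k-subsets of the doubled ranks with sum s
    maxs = int(r2.sum())
    table = np.zeros((n1 + 1, maxs + 1))
    table[0, 0] = 1.0
    for r in r2:
        r = int(r)
        for k in range(n1, 0, -1):
            table[k, r:] += table[k - 1, : maxs + 1 - r]
    dist = table[n1]
    total = dist.sum()  # == C(N, n1)
    center = n1 * (N + 1)  # expected doubled rank sum
    dev = abs(s_obs - center)
    sums = np.arange(maxs + 1)
    p = dist[np.abs(sums - center) >= dev - 1e-9].sum() / total
    return u_obs, float(min(1.0, p))


def mann_whitney_two_sided(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation null (tie-aware, via midrank DP) when the
    smaller sample has <= 8 observations and the pooled sample is small
    enough to tabulate; otherwise the normal approximation with continuity
    and tie correction.  Returns (U of x vs y, two-sided P).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if min(len(x), len(y)) <= EXACT_MIN_N and len(x) + len(y) <= EXACT_MAX_TOTAL:
        return _exact_two_sided(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# organ-normalized correlation


def organ_normalized_correlation(
    mirna_matrix: pd.DataFrame,
    trigger_matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    whole_body_col: str = "whole_body",
    log2: bool = False,
) -> tuple[pd.DataFrame, float, float | None]:
    """Whole-body abundance normalized by the mean across organs, per
    entity, then pooled Pearson correlation over (miRNA, trigger) pairs.

    Both matrices are entities x (organs + whole-body) abundances.  Pairs
    with a zero organ mean are skipped with a warning row; with fewer than
    3 usable pairs r is reported and P withheld.  ``log2`` computes the
    correlation on log2-transformed normalized values.
    """
    organ_cols_m = [c for c in mirna_matrix.columns if c != whole_body_col]
    organ_cols_t = [c for c in trigger_matrix.columns if c != whole_body_col]
    if len(organ_cols_m) < 2 or len(organ_cols_t) < 2:
        raise ValueError("need >= 2 organ columns besides the whole-body column")
    rows = []
    for mid, tid in pairs:
        m_org = mirna_matrix.loc[mid, organ_cols_m].astype(float)
        t_org = trigger_matrix.loc[tid, organ_cols_t].astype(float)
        if m_org.mean() == 0 or t_org.mean() == 0:
            rows.append((mid, tid, math.nan, math.nan, True))
            continue
        m_norm = float(mirna_matrix.loc[mid, whole_body_col]) / m_org.mean()
        t_norm = float(trigger_matrix.loc[tid, whole_body_col]) / t_org.mean()
        if log2:
            m_norm, t_norm = math.log2(m_norm), math.log2(t_norm)
        rows.append((mid, tid, m_norm, t_norm, False))
    table = pd.DataFrame(
        rows, columns=["mirna", "trigger", "mirna_norm", "trigger_norm", "skipped"]
    )
    ok = table[~table["skipped"]]
    if len(ok) < 2:
        raise ValueError("fewer than 2 usable pairs")
    xs, ys = ok["mirna_norm"].to_numpy(), ok["trigger_norm"].to_numpy()
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance in normalized abundances")
    r, p = stats.pearsonr(xs, ys)
    if len(ok) < 3:
        return table, float(r), None
    return table, float(r), float(p)
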