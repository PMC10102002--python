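"""Independent oracles used by the test-suite and the acceptance script.

Each oracle re-derives an expected result by a route that shares no code
with the implementation it checks: exhaustive enumeration for duplex
folding and the rank test, a literal re-reading of the screening rules for
the classifier, and direct formulas for the normalization.
"""

from __future__ import annotations

import itertools
import math
import statistics

from scipy.stats import rankdata

from tdmdscreen.duplex_fold import DEFAULT_MODEL


def oracle_fold(a: str, b: str, model=DEFAULT_MODEL) -> tuple[float, int]:
    """Minimum duplex energy by brute-force DFS over every valid non-empty
    antiparallel pairing (intended for sequences of length <= 10).

    Returns (energy in tenths of kcal/mol, pair count at the optimum with
    the more-pairs tie-break).  (inf, 0) when no pair is admissible.
    """
    M, T = len(a), len(b)
    w = [[model.weight_tenths(a[i], b[j]) for j in range(T)] for i in range(M)]
    init = round(model.init * 10)
    b_open, b_per = round(model.bulge_open * 10), round(model.bulge_per_nt * 10)
    il_open = round(model.iloop_open * 10)
    il_per, il_asym = round(model.iloop_per_nt * 10), round(model.iloop_asym * 10)
    best: list[tuple[float, int]] = [(math.inf, 0)]

    def gap_cost(pi: int, pj: int, i: int, j: int) -> int | None:
        gm, gt = i - pi - 1, pj - j - 1
        if gm > model.max_loop or gt > model.max_loop:
            return None
        if gm == 0 and gt == 0:
            return -(w[pi][pj] + w[i][j]) // 2
        if gm == 0 or gt == 0:
            return b_open + b_per * (gm + gt)
        return il_open + il_per * (gm + gt) + il_asym * abs(gm - gt)

    def dfs(i: int, j: int, e: int, n: int) -> None:
        if (e, -n) < (best[0][0], -best[0][1]):
            best[0] = (e, n)
        for i2 in range(i + 1, min(M, i + 2 + model.max_loop)):
            for j2 in range(max(0, j - 1 - model.max_loop), j):
                if w[i2][j2] is None:
                    continue
                c = gap_cost(i, j, i2, j2)
                if c is not None:
                    dfs(i2, j2, e + c, n + 1)

    for i in range(M):
        for j in range(T):
            if w[i][j] is not None:
                dfs(i, j, init, 1)
    return best[0]


def oracle_mw_two_sided(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney P by enumerating every assignment of the
    pooled (midranked) observations to the first sample."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = x + y
    ranks = rankdata(pooled)
    mu = n1 * n2 / 2

    def u_of(idx) -> float:
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    d_obs = abs(u_obs - mu)
    total = hits = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(comb) - mu) >= d_obs - 1e-9:
            hits += 1
    return u_obs, hits / total


def oracle_tdmd_rules(
    pairs, mirna_length: int, dg: float, dg_max: float = -16.0
) -> dict[str, bool]:
    """Literal re-evaluation of the four screening rules from a pair list.

    Written directly from the rule statements, operating on position sets
    rather than on helices/profiles: seed = positions 2-8 all paired;
    3' = the last 8 positions all paired, or a >=9 run of consecutive
    paired positions reaching into the last 8; central = the unpaired
    stretch (max of the two strands) between the seed-region pairing and
    the next pairing block is in 1..6; energy = dg <= dg_max.
    """
    paired = {i for i, _, _ in pairs}
    target_of = {i: j for i, j, _ in pairs}
    L = mirna_length
    seed_ok = all(p in paired for p in range(2, 9))

    window = set(range(L - 7, L + 1))
    three_ok = window <= paired
    if not three_ok:
        run: list[int] = []
        for p in range(1, L + 2):
            if p in paired and p <= L:
                run.append(p)
            else:
                if len(run) >= 9 and set(run) & window:
                    three_ok = True
                run = []

    # central loop: blocks of consecutive paired positions with strictly
    # consecutive target partners
    blocks: list[list[int]] = []
    for p in sorted(paired):
        if (
            blocks
            and p == blocks[-1][-1] + 1
            and target_of[p] == target_of[blocks[-1][-1]] - 1
        ):
            blocks[-1].append(p)
        else:
            blocks.append([p])
    seed_block = next((b for b in blocks if set(b) & set(range(2, 9))), None)
    loop = math.inf
    if seed_block is not None:
        after = [b for b in blocks if b[0] > seed_block[-1]]
        if after:
            nxt = after[0]
            loop = max(
                nxt[0] - seed_block[-1] - 1,
                target_of[seed_block[-1]] - target_of[nxt[0]] - 1,
            )
        elif seed_block[-1] >= L - 7:
            loop = 0
    central_ok = 1 <= loop <= 6

    return {
        "seed": seed_ok,
        "three_prime": three_ok,
        "central": central_ok,
        "energy": dg <= dg_max,
        "candidate": seed_ok and three_ok and central_ok and (dg <= dg_max),
    }


def oracle_size_factors(counts) -> list[float]:
    """Median-of-ratios by direct per-cell loops (no numpy)."""
    n_genes = len(counts)
    n_samples = len(counts[0])
    usable = [
        g for g in range(n_genes) if all(counts[g][s] > 0 for s in range(n_samples))
    ]
    factors = []
    for s in range(n_samples):
        ratios = []
        for g in usable:
            geo = math.exp(
                sum(math.log(counts[g][t]) for t in range(n_samples)) / n_samples
            )
            ratios.append(counts[g][s] / geo)
        factors.append(statistics.median(ratios))
    return factors
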