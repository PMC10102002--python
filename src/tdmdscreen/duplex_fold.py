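"""Intermolecular RNA duplex folding under a documented nearest-neighbor-style
energy model.

The model scores an antiparallel duplex between a miRNA (5'->3') and a
target site (5'->3'): allowed pairs are Watson-Crick (AU/UA/GC/CG) and,
optionally, G-U wobbles.  Energy = duplex initiation + one stacking term per
adjacent pair + bulge / internal-loop penalties; unpaired end overhangs are
free and neither strand folds on itself.  The dynamic program is exact
(globally optimal) for this model.

Energies are handled internally in integer tenths of kcal/mol so that
optima and ties are exact; model parameters are rounded to the 0.1 grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def pair_type(a: str, b: str, gu_allowed: bool = True) -> str | None:
    """Classify a base pair: 'WC', 'GU', or None if unpairable."""
    if (a, b) in _WC:
        return "WC"
    if gu_allowed and (a, b) in _GU:
        return "GU"
    return None


@dataclass(frozen=True)
class EnergyModel:
    """Tunable parameters of the duplex energy model (kcal/mol).

    ``pair_weights`` maps a pair class to a positive stability weight w;
    each stacked adjacent pair (p, q) contributes -(w(p) + w(q)) / 2.
    A bulge of b unpaired nt costs ``bulge_open + bulge_per_nt * b``; an
    internal loop of (l1, l2) costs
    ``iloop_open + iloop_per_nt * (l1 + l2) + iloop_asym * |l1 - l2|``.
    ``init`` is the duplex initiation cost; ``max_loop`` caps the unpaired
    stretch per side between two consecutive pairs.
    """

    pair_weights: dict[str, float] = field(
        default_factory=lambda: {"GC": 3.0, "AU": 2.0, "GU": 1.0}
    )
    bulge_open: float = 3.0
    bulge_per_nt: float = 0.5
    iloop_open: float = 2.0
    iloop_per_nt: float = 0.5
    iloop_asym: float = 0.5
    init: float = 4.1
    gu_allowed: bool = True
    max_loop: int = 10

    def weight_tenths(self, a: str, b: str) -> int | None:
        """Stability weight of pair (a, b) in tenths, or None if unpairable."""
        pt = pair_type(a, b, self.gu_allowed)
        if pt is None:
            return None
        key = "GU" if pt == "GU" else ("GC" if a in "GC" else "AU")
        return round(self.pair_weights[key] * 10)


DEFAULT_MODEL = EnergyModel()


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs: consecutive miRNA positions paired to
    strictly consecutive (descending) target positions.  1-based inclusive."""

    mirna_start: int
    mirna_end: int
    target_hi: int  # target partner of mirna_start (largest, 5'-proximal pair)
    target_lo: int  # target partner of mirna_end


@dataclass(frozen=True)
class DuplexStructure:
    """An antiparallel miRNA:target duplex.

    ``pairs`` holds (mirna_pos, target_pos, pair_type) 1-based, strictly
    increasing in mirna_pos and strictly decreasing in target_pos.
    ``central_loop`` is the (miRNA-side, target-side) unpaired count between
    the seed-proximal helix and the nearest helix 3' of it; ``math.inf``
    components encode "no 3' helix" (seed-only structures).
    """

    mirna_length: int
    target_length: int
    pairs: tuple[tuple[int, int, str], ...]
    dg: float
    paired: tuple[bool, ...] = ()
    helices: tuple[Helix, ...] = ()
    central_loop: tuple[float, float] = (math.inf, math.inf)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def render(self) -> str:
        """Two-line diagram: miRNA 5'->3' on top, '|' WC pairs, ':' wobbles."""
        by_mirna = {i: pt for i, _, pt in self.pairs}
        marks = "".join(
            "|" if by_mirna.get(i) == "WC" else (":" if by_mirna.get(i) == "GU" else ".")
            for i in range(1, self.mirna_length + 1)
        )
        return marks


def _check_rna(seq: str, what: str) -> None:
    if not RNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise ValueError(f"{what}: invalid characters {bad} (RNA A/C/G/U expected)")


def fold_duplex(
    mirna_seq: str, target_seq: str, model: EnergyModel = DEFAULT_MODEL
) -> DuplexStructure:
    """Minimum-energy antiparallel duplex between ``mirna_seq`` and
    ``target_seq`` (both 5'->3').

    Returns the globally optimal structure under ``model``; ties are broken
    toward more pairs, then toward the lexicographically smaller pair list.
    If no admissible pair exists the structure is empty with dg 0 (weak
    duplexes whose optimum is dominated by the initiation cost keep their
    positive dg).
    """
    _check_rna(mirna_seq, "miRNA")
    _check_rna(target_seq, "target")
    M, T = len(mirna_seq), len(target_seq)
    w = model.weight_tenths
    init = round(model.init * 10)
    b_open, b_per = round(model.bulge_open * 10), round(model.bulge_per_nt * 10)
    il_open = round(model.iloop_open * 10)
    il_per, il_asym = round(model.iloop_per_nt * 10), round(model.iloop_asym * 10)
    maxloop = model.max_loop

    # pair weight per cell; None = unpairable
    pw = [[w(mirna_seq[i], target_seq[j]) for j in range(T)] for i in range(M)]

    INF = float("inf")
    # E[i][j]: best energy (tenths) of a duplex whose LAST pair is (i, j)
    E = [[INF] * T for _ in range(M)]
    NP = [[0] * T for _ in range(M)]
    BP: list[list[tuple[int, int] | None]] = [[None] * T for _ in range(M)]

    for i in range(M):
        Ei, NPi, BPi, pwi = E[i], NP[i], BP[i], pw[i]
        for j in range(T):
            wij = pwi[j]
            if wij is None:
                continue
            best_e, best_np, best_bp = init, 1, None
            for pi in range(max(0, i - 1 - maxloop), i):
                Ep, NPp, pwp = E[pi], NP[pi], pw[pi]
                gm = i - pi - 1
                for pj in range(j + 1, min(T, j + 2 + maxloop)):
                    e_prev = Ep[pj]
                    if e_prev == INF:
                        continue
                    gt = pj - j - 1
                    if gm == 0 and gt == 0:
                        cost = -(pwp[pj] + wij) // 2
                    elif gm == 0 or gt == 0:
                        cost = b_open + b_per * (gm + gt)
                    else:
                        cost = il_open + il_per * (gm + gt) + il_asym * abs(gm - gt)
                    e = e_prev + cost
                    n = NPp[pj] + 1
                    if e < best_e or (e == best_e and n > best_np):
                        best_e, best_np, best_bp = e, n, (pi, pj)
            Ei[j], NPi[j], BPi[j] = best_e, best_np, best_bp

    # global optimum over all last-pair cells; prefer lower energy, more
    # pairs, then the smaller (i, j) cell for determinism
    best: tuple[float, int, tuple[int, int]] | None = None
    for i in range(M):
        for j in range(T):
            if pw[i][j] is None or E[i][j] == INF:
                continue
            cand = (E[i][j], -NP[i][j], (i, j))
            if best is None or cand < best:
                best = cand
    if best is None:
        return DuplexStructure(M, T, (), 0.0, tuple([False] * M))

    # reconstruct the pair list (stored back-to-front)
    cell: tuple[int, int] | None = best[2]
    rev: list[tuple[int, int]] = []
    while cell is not None:
        rev.append(cell)
        cell = BP[cell[0]][cell[1]]
    pairs = tuple(
        (i + 1, j + 1, pair_type(mirna_seq[i], target_seq[j], model.gu_allowed))
        for i, j in reversed(rev)
    )
    dg = best[0] / 10.0
    profile = pairing_profile(pairs, M)
    return DuplexStructure(
        M, T, pairs, dg, profile.paired, profile.helices, profile.central_loop
    )


@dataclass(frozen=True)
class PairingProfile:
    """Features of a duplex consumed by the TDMD structural criteria."""

    mirna_length: int
    paired: tuple[bool, ...]  # index 0 = miRNA position 1
    helices: tuple[Helix, ...]
    central_loop: tuple[float, float]  # (miRNA side, target side); inf = none

    def is_paired(self, pos: int) -> bool:
        """1-based miRNA position."""
        return self.paired[pos - 1]


SEED_SPAN = (2, 8)


def pairing_profile(
    pairs: tuple[tuple[int, int, str], ...] | list, mirna_length: int
) -> PairingProfile:
    """Derive the paired vector, helix list and central loop from a pair list.

    Helices are maximal runs of consecutive miRNA positions paired to
    strictly consecutive target positions.  The central loop sits between
    the seed-proximal helix (the 5'-most helix touching miRNA positions 2-8)
    and the nearest helix 3' of it: its miRNA side counts unpaired miRNA
    positions strictly between the two helices, its target side unpaired
    target positions between their footprints.  A single helix that runs
    from the seed into the last-8 window has central loop (0, 0) (perfect
    duplex); a seed-only structure has (inf, inf).
    """
    paired = [False] * mirna_length
    for i, _, _ in pairs:
        paired[i - 1] = True

    helices: list[Helix] = []
    if pairs:
        start = 0
        for k in range(1, len(pairs) + 1):
            if (
                k == len(pairs)
                or pairs[k][0] != pairs[k - 1][0] + 1
                or pairs[k][1] != pairs[k - 1][1] - 1
            ):
                helices.append(
                    Helix(
                        mirna_start=pairs[start][0],
                        mirna_end=pairs[k - 1][0],
                        target_hi=pairs[start][1],
                        target_lo=pairs[k - 1][1],
                    )
                )
                start = k

    lo, hi = SEED_SPAN
    seed_helix = next(
        (h for h in helices if h.mirna_start <= hi and h.mirna_end >= lo), None
    )
    central: tuple[float, float] = (math.inf, math.inf)
    if seed_helix is not None:
        nxt = next((h for h in helices if h.mirna_start > seed_helix.mirna_end), None)
        if nxt is not None:
            central = (
                float(nxt.mirna_start - seed_helix.mirna_end - 1),
                float(seed_helix.target_lo - nxt.target_hi - 1),
            )
        elif seed_helix.mirna_end >= mirna_length - 7:
            central = (0.0, 0.0)
    return PairingProfile(mirna_length, tuple(paired), tuple(helices), central)
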